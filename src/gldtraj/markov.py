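"""Piecewise-constant continuous-time multi-state Markov model.

States are the annual treatment-change categories NC / IN / DI observed
as panel data at the yearly anniversaries.  Within each one-year
inter-observation interval the process is assumed to be a homogeneous
continuous-time Markov chain with generator (intensity) matrix Q, so the
one-year transition probability matrix is P(1) = exp(Q).  Intensities
are piecewise constant: each of the four inter-observation intervals
(Year 1→2 … Year 4→5) gets its own generator, estimated by maximum
likelihood on the observed transition counts via the matrix-exponential
likelihood, optimising log intensities (unconstrained) with analytic
gradients from the Fréchet derivative of the matrix exponential.

Confidence intervals for the transition probabilities come from a
seeded parametric bootstrap over the asymptotic normal of the
log-intensities (default), or from the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm, expm_frechet
from scipy.optimize import minimize

from .change import STATES
from .config import MarkovConfig

N_STATES = 3
_OFFDIAG = [(i, j) for i in range(N_STATES) for j in range(N_STATES) if i != j]
_THETA_LO, _THETA_HI = -12.0, 3.0  # log-intensity bounds: q in [6e-6, ~20]


def generator_from_theta(theta: np.ndarray) -> np.ndarray:
    q = np.zeros((N_STATES, N_STATES))
    for (i, j), t in zip(_OFFDIAG, theta):
        q[i, j] = np.exp(t)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def validate_generator(q: np.ndarray) -> None:
    q = np.asarray(q, dtype=float)
    if q.shape != (N_STATES, N_STATES):
        raise ValueError("generator must be 3x3")
    off = q[~np.eye(N_STATES, dtype=bool)]
    if np.any(off < 0):
        raise ValueError("off-diagonal intensities must be non-negative")
    if np.max(np.abs(q.sum(axis=1))) > 1e-8:
        raise ValueError("generator rows must sum to zero")


@dataclass
class ProbabilityMatrix:
    p: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def frame(self, interval_index: int | None = None) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(STATES):
            for j, b in enumerate(STATES):
                row = {"from_state": a, "to_state": b, "probability": self.p[i, j]}
                if interval_index is not None:
                    row = {"interval_index": interval_index} | row
                if self.ci_low is not None:
                    row["ci_low"] = self.ci_low[i, j]
                    row["ci_high"] = self.ci_high[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def transition_probability(q: np.ndarray, t: float = 1.0) -> ProbabilityMatrix:
    """P(t) = exp(Qt) for a valid generator (row-stochastic by construction)."""
    validate_generator(q)
    return ProbabilityMatrix(p=expm(np.asarray(q, dtype=float) * t))


def counts_from_panel(panel: pd.DataFrame) -> tuple[np.ndarray, list[np.ndarray]]:
    """Initial-state counts and per-piece transition count matrices.

    ``panel`` is a wide frame: one row per patient, columns the observed
    state at years 1..T (strings NC/IN/DI).
    """
    cols = list(panel.columns)
    sidx = {s: i for i, s in enumerate(STATES)}
    arr = panel[cols].apply(lambda c: c.map(sidx)).to_numpy()
    if np.isnan(arr.astype(float)).any():
        raise ValueError("panel contains states outside {NC, IN, DI}")
    arr = arr.astype(int)
    init = np.bincount(arr[:, 0], minlength=N_STATES).astype(float)
    pieces = []
    for k in range(arr.shape[1] - 1):
        n = np.zeros((N_STATES, N_STATES))
        np.add.at(n, (arr[:, k], arr[:, k + 1]), 1.0)
        pieces.append(n)
    return init, pieces


def piece_loglik(theta: np.ndarray, counts: np.ndarray,
                 grad: bool = False):
    """Multinomial matrix-exponential log likelihood for one piece."""
    q = generator_from_theta(theta)
    p = expm(q)
    mask = counts > 0
    if np.any(p[mask] <= 0):
        return (-np.inf, np.zeros_like(theta)) if grad else -np.inf
    ll = float(np.sum(counts[mask] * np.log(p[mask])))
    if not grad:
        return ll
    w = np.where(mask, counts / np.where(p > 0, p, 1.0), 0.0)
    g = np.empty(len(theta))
    for m, (i, j) in enumerate(_OFFDIAG):
        e = np.zeros((N_STATES, N_STATES))
        e[i, j] = 1.0
        e[i, i] = -1.0
        dp = expm_frechet(q, e, compute_expm=False)
        g[m] = np.exp(theta[m]) * float(np.sum(w * dp))
    return ll, g


def log_likelihood(panel: pd.DataFrame, generators: list[np.ndarray]) -> float:
    """Panel log likelihood under per-piece generators (1-year gaps).

    A transition observed with probability zero contributes −inf (the
    value is returned, not raised).
    """
    _, pieces = counts_from_panel(panel)
    if len(generators) != len(pieces):
        raise ValueError(
            f"need one generator per interval: {len(pieces)} intervals, "
            f"{len(generators)} generators"
        )
    total = 0.0
    for counts, q in zip(pieces, generators):
        validate_generator(q)
        p = expm(np.asarray(q, dtype=float))
        mask = counts > 0
        if np.any(p[mask] <= 0):
            warnings.warn("observed transition has zero probability; -inf")
            return -np.inf
        total += float(np.sum(counts[mask] * np.log(p[mask])))
    return total


@dataclass
class PieceFit:
    q: np.ndarray
    theta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    cov_theta: np.ndarray | None = None


@dataclass
class MarkovFit:
    pieces: list[PieceFit]
    probabilities: list[ProbabilityMatrix]
    initial_counts: np.ndarray
    counts: list[np.ndarray]
    config: MarkovConfig = field(default_factory=MarkovConfig)

    @property
    def converged(self) -> bool:
        return all(p.converged for p in self.pieces)

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "interval_index": k + 1,
                    "loglik": p.loglik,
                    "converged": p.converged,
                    "n_iter": p.n_iter,
                    "grad_norm": p.grad_norm,
                }
                for k, p in enumerate(self.pieces)
            ]
        )

    def frame(self) -> pd.DataFrame:
        return pd.concat(
            [pm.frame(k + 1) for k, pm in enumerate(self.probabilities)],
            ignore_index=True,
        )


def _init_theta(counts: np.ndarray) -> np.ndarray:
    row = counts.sum(axis=1)
    theta = np.empty(len(_OFFDIAG))
    for m, (i, j) in enumerate(_OFFDIAG):
        rate = (counts[i, j] + 0.5) / (row[i] + 0.5)  # continuity-corrected
        theta[m] = np.log(max(rate, 1e-6))
    return np.clip(theta, _THETA_LO + 1e-9, _THETA_HI - 1e-9)


def fit_piece(counts: np.ndarray, config: MarkovConfig | None = None) -> PieceFit:
    """Maximum-likelihood generator for one interval's transition counts."""
    config = config or MarkovConfig()
    counts = np.asarray(counts, dtype=float)

    def neg(theta):
        ll, g = piece_loglik(theta, counts, grad=True)
        return -ll, -g

    theta0 = _init_theta(counts)
    res = minimize(
        neg, theta0, jac=True, method="L-BFGS-B",
        bounds=[(_THETA_LO, _THETA_HI)] * len(theta0),
        options={"maxiter": config.max_iter, "ftol": 1e-14,
                 "gtol": config.gtol},
    )
    ll, g = piece_loglik(res.x, counts, grad=True)
    return PieceFit(
        q=generator_from_theta(res.x),
        theta=res.x,
        loglik=ll,
        converged=bool(res.success),
        n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(g))),
    )


def _hessian(theta: np.ndarray, counts: np.ndarray, step: float = 1e-5) -> np.ndarray:
    n = len(theta)
    h = np.zeros((n, n))
    for m in range(n):
        tp = theta.copy(); tp[m] += step
        tm = theta.copy(); tm[m] -= step
        _, gp = piece_loglik(tp, counts, grad=True)
        _, gm = piece_loglik(tm, counts, grad=True)
        h[m] = (gp - gm) / (2 * step)
    h = 0.5 * (h + h.T)
    return -h  # observed information


def _cov_theta(theta, counts):
    """Asymptotic covariance of the log-intensities.

    Parameters that ended on a box bound (intensities driven to zero, or
    directions the data cannot identify) are treated as fixed: their
    rows/columns are zeroed so the uncertainty propagation does not wander
    along flat likelihood directions.
    """
    free = (theta > _THETA_LO + 1e-6) & (theta < _THETA_HI - 1e-6)
    cov = np.zeros((len(theta), len(theta)))
    if free.any():
        info = _hessian(theta, counts)[np.ix_(free, free)]
        info = info + 1e-10 * np.eye(info.shape[0])
        try:
            sub = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            sub = np.linalg.pinv(info)
        cov[np.ix_(free, free)] = sub
    return cov


def _bootstrap_ci(piece: PieceFit, draws: int, rng: np.random.Generator):
    cov = piece.cov_theta
    # guard against slight non-PSD from finite differences
    w, v = np.linalg.eigh(0.5 * (cov + cov.T))
    cov = (v * np.clip(w, 0.0, None)) @ v.T
    thetas = rng.multivariate_normal(piece.theta, cov, size=draws,
                                     method="cholesky" if np.all(w > 0) else "svd")
    thetas = np.clip(thetas, _THETA_LO, _THETA_HI)
    ps = np.empty((draws, N_STATES, N_STATES))
    for b in range(draws):
        ps[b] = expm(generator_from_theta(thetas[b]))
    lo = np.quantile(ps, 0.025, axis=0)
    hi = np.quantile(ps, 0.975, axis=0)
    return lo, hi


def _delta_ci(piece: PieceFit):
    """Delta-method 95% CI: propagate cov(theta) through expm."""
    q = piece.q
    jac = np.empty((len(_OFFDIAG), N_STATES, N_STATES))
    for m, (i, j) in enumerate(_OFFDIAG):
        e = np.zeros((N_STATES, N_STATES))
        e[i, j] = 1.0
        e[i, i] = -1.0
        jac[m] = q[i, j] * expm_frechet(q, e, compute_expm=False)
    p = expm(q)
    var = np.einsum("mij,mn,nij->ij", jac, piece.cov_theta, jac)
    sd = np.sqrt(np.clip(var, 0.0, None))
    lo = np.clip(p - 1.96 * sd, 0.0, 1.0)
    hi = np.clip(p + 1.96 * sd, 0.0, 1.0)
    return lo, hi


def fit(panel_or_counts, config: MarkovConfig | None = None,
        compute_ci: bool = True) -> MarkovFit:
    """Fit per-interval generators by ML and derive 1-year probabilities.

    ``panel_or_counts`` is either a wide panel frame (rows = patients,
    columns = annual states) or a list of 3x3 transition-count matrices.
    """
    config = config or MarkovConfig()
    if isinstance(panel_or_counts, pd.DataFrame):
        if panel_or_counts.empty:
            raise ValueError("panel is empty")
        init, pieces_counts = counts_from_panel(panel_or_counts)
        seen = init.copy()
        for c in pieces_counts:
            seen += c.sum(axis=0)
        if np.any(seen == 0):
            warnings.warn(
                "degenerate panel: some state never observed; its "
                "intensities are unidentified"
            )
    else:
        pieces_counts = [np.asarray(c, dtype=float) for c in panel_or_counts]
        init = pieces_counts[0].sum(axis=1)

    rng = np.random.default_rng(config.seed)
    piece_fits, probs = [], []
    for counts in pieces_counts:
        pf = fit_piece(counts, config)
        p = expm(pf.q)
        if compute_ci:
            pf.cov_theta = _cov_theta(pf.theta, counts)
            if config.ci_method == "bootstrap":
                lo, hi = _bootstrap_ci(pf, config.bootstrap_draws, rng)
            else:
                lo, hi = _delta_ci(pf)
            lo = np.minimum(lo, p)
            hi = np.maximum(hi, p)
            probs.append(ProbabilityMatrix(p=p, ci_low=lo, ci_high=hi))
        else:
            probs.append(ProbabilityMatrix(p=p))
        piece_fits.append(pf)
    return MarkovFit(
        pieces=piece_fits,
        probabilities=probs,
        initial_counts=init,
        counts=pieces_counts,
        config=config,
    )


def goodness_of_fit(panel_or_counts, fitted: MarkovFit) -> pd.DataFrame:
    """Observed vs expected transition counts per piece, with Pearson
    residuals; expected = (row marginal at piece start) x fitted P."""
    if isinstance(panel_or_counts, pd.DataFrame):
        _, counts = counts_from_panel(panel_or_counts)
    else:
        counts = [np.asarray(c, dtype=float) for c in panel_or_counts]
    rows = []
    for k, (n, pm) in enumerate(zip(counts, fitted.probabilities), start=1):
        marg = n.sum(axis=1)
        expected = marg[:, None] * pm.p
        with np.errstate(divide="ignore", invalid="ignore"):
            resid = np.where(expected > 0, (n - expected) / np.sqrt(expected), 0.0)
        for i, a in enumerate(STATES):
            for j, b in enumerate(STATES):
                rows.append(
                    {
                        "interval_index": k,
                        "from_state": a,
                        "to_state": b,
                        "observed": n[i, j],
                        "expected": expected[i, j],
                        "pearson_residual": resid[i, j],
                    }
                )
    return pd.DataFrame(rows)


def simulate_panel(
    rng: np.random.Generator,
    n_patients: int,
    initial_dist: np.ndarray,
    p_pieces: list[np.ndarray],
) -> pd.DataFrame:
    """Sample a panel of annual states from known 1-year transition matrices."""
    initial_dist = np.asarray(initial_dist, dtype=float)
    initial_dist = initial_dist / initial_dist.sum()
    cur = rng.choice(N_STATES, size=n_patients, p=initial_dist)
    cols = {1: cur}
    for k, p in enumerate(p_pieces, start=2):
        cum = np.cumsum(p, axis=1)
        u = rng.random(n_patients)
        cur = (u[:, None] > cum[cur]).sum(axis=1)
        cols[k] = cur
    data = {f"y{k}": [STATES[s] for s in v] for k, v in cols.items()}
    return pd.DataFrame(data)


def plot_transition_network(fitted: MarkovFit, path) -> None:
    """Simple per-interval network rendering (nodes NC/IN/DI, edges
    labelled with 1-year probabilities)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = {0: (0.0, 1.0), 1: (-0.9, -0.6), 2: (0.9, -0.6)}
    k_pieces = len(fitted.probabilities)
    fig, axes = plt.subplots(1, k_pieces, figsize=(4 * k_pieces, 4))
    if k_pieces == 1:
        axes = [axes]
    for k, (ax, pm) in enumerate(zip(axes, fitted.probabilities), start=1):
        for i, s in enumerate(STATES):
            ax.scatter(*pos[i], s=1600, c="#cfe8cf", zorder=2)
            ax.annotate(s, pos[i], ha="center", va="center", zorder=3)
            ax.annotate(f"{pm.p[i, i]:.2f}",
                        (pos[i][0], pos[i][1] + 0.28), ha="center", fontsize=8)
        for i in range(N_STATES):
            for j in range(N_STATES):
                if i == j:
                    continue
                x0, y0 = pos[i]
                x1, y1 = pos[j]
                ax.annotate(
                    "", xy=(x1, y1), xytext=(x0, y0),
                    arrowprops={"arrowstyle": "-|>", "color": "0.5",
                                "shrinkA": 22, "shrinkB": 22},
                )
                ax.annotate(
                    f"{pm.p[i, j]:.2f}",
                    ((x0 + 2 * x1) / 3, (y0 + 2 * y1) / 3 + 0.05),
                    fontsize=7, color="0.3", ha="center",
                )
        ax.set_title(f"Year {k}→{k + 1}")
        ax.set_xlim(-1.4, 1.4)
        ax.set_ylim(-1.2, 1.6)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
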