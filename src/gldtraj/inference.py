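"""Multinomial logistic regression of the 5-year net outcome.

Outcome: net treatment change after five years (NC reference, IN, DI).
Model 1 regresses on hypoglycemia risk category (low reference), sex
(male reference) and age per 10 years; Model 2 on risk category only.
Fitted by Newton-type maximum likelihood (statsmodels MNLogit); odds
ratios with two-sided 95% Wald confidence intervals, flagged significant
at p < 0.05.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .change import STATES

MODEL_PREDICTORS = {1: ["high_risk", "female", "age_decades"], 2: ["high_risk"]}

_PRETTY = {
    "high_risk": ("Hypoglycemia risk category", "High risk"),
    "female": ("Sex", "Female"),
    "age_decades": ("Age", "Per 10 years"),
}


class SeparationError(RuntimeError):
    """Raised when a coefficient is unbounded (perfect separation) or the
    design matrix is rank deficient."""


def build_design(
    members: pd.DataFrame,
    outcomes: pd.DataFrame,
    risk_scores: pd.DataFrame,
) -> pd.DataFrame:
    """One row per patient: outcome label and coded predictors."""
    df = members.merge(outcomes, on="patient_id").merge(
        risk_scores[["patient_id", "category"]], on="patient_id"
    )
    return pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "outcome": pd.Categorical(df["outcome"], categories=STATES),
            "high_risk": (df["category"] == "high").astype(float),
            "female": (df["sex"] == "female").astype(float),
            "age_decades": df["age_at_index"] / 10.0,
        }
    )


def fit_multinomial(design: pd.DataFrame, model_id: int = 1):
    """Fit one model; returns (ORTable frame, coefficient frame, loglik).

    NC is the baseline outcome; ORs are exponentiated coefficients with
    Wald 95% CIs from the observed information matrix.
    """
    if model_id not in MODEL_PREDICTORS:
        raise ValueError("model_id must be 1 or 2")
    preds = MODEL_PREDICTORS[model_id]
    observed = design["outcome"].value_counts()
    if (observed > 0).sum() < 2:
        raise ValueError("outcome must have at least two observed categories")
    x = design[preds].to_numpy(dtype=float)
    for k, name in enumerate(preds):
        if np.ptp(x[:, k]) == 0:
            raise SeparationError(f"predictor {name!r} is constant")
    exog = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise SeparationError("design matrix is rank deficient (collinearity)")
    y = pd.Categorical(design["outcome"], categories=STATES).codes
    observed_codes = np.unique(y)  # MNLogit drops unobserved categories
    if observed_codes[0] != 0:
        raise ValueError("reference outcome NC was never observed")
    fit_outcomes = [STATES[c] for c in observed_codes[1:]]
    model = sm.MNLogit(y, exog)
    try:
        res = model.fit(method="newton", maxiter=200, disp=False)
    except np.linalg.LinAlgError as exc:
        raise SeparationError(
            "singular information matrix during fitting (perfect "
            "separation or degenerate design)"
        ) from exc
    params = np.asarray(res.params)  # (k_exog, 2): columns IN, DI vs NC
    if np.any(np.abs(params[1:, :]) > 15):
        k = int(np.argmax(np.abs(params[1:, :]).max(axis=1)))
        raise SeparationError(
            f"unbounded coefficient for predictor {preds[k]!r} "
            "(perfect separation)"
        )
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)

    names = ["intercept"] + preds
    rows = []
    coef_rows = []
    for j, outcome in enumerate(fit_outcomes):  # IN and/or DI vs NC
        for k, name in enumerate(names):
            b, se, p = params[k, j], bse[k, j], pvals[k, j]
            coef_rows.append(
                {"outcome": outcome, "predictor": name, "coef": b,
                 "se": se, "p_value": p}
            )
            if name == "intercept":
                continue
            factor, level = _PRETTY[name]
            rows.append(
                {
                    "model": model_id,
                    "outcome": outcome,
                    "factor": factor,
                    "level": level,
                    "odds_ratio": float(np.exp(b)),
                    "ci_low": float(np.exp(b - 1.96 * se)),
                    "ci_high": float(np.exp(b + 1.96 * se)),
                    "p_value": float(p),
                    "significant": bool(p < 0.05),
                }
            )
    or_table = pd.DataFrame(rows)
    coef_table = pd.DataFrame(coef_rows)
    return or_table, coef_table, float(res.llf)


def fit_models(design: pd.DataFrame) -> pd.DataFrame:
    """Model 1 (risk + sex + age) and Model 2 (risk only), stacked."""
    tables = []
    for model_id in (1, 2):
        t, _, _ = fit_multinomial(design, model_id)
        tables.append(t)
    return pd.concat(tables, ignore_index=True)


def simulate_outcomes(
    rng: np.random.Generator,
    n: int,
    frac_high: float,
    intercepts: tuple[float, float],
    log_or_high: tuple[float, float],
) -> pd.DataFrame:
    """Draw (outcome, high_risk) rows from an exact multinomial-logit law.

    ``intercepts`` and ``log_or_high`` are the (IN, DI) linear-predictor
    parameters relative to the NC baseline — the ground truth for
    parameter-recovery and CI-coverage simulations.
    """
    high = (rng.random(n) < frac_high).astype(float)
    eta_in = intercepts[0] + log_or_high[0] * high
    eta_di = intercepts[1] + log_or_high[1] * high
    denom = 1.0 + np.exp(eta_in) + np.exp(eta_di)
    p_nc = 1.0 / denom
    p_in = np.exp(eta_in) / denom
    u = rng.random(n)
    outcome = np.where(u < p_nc, "NC", np.where(u < p_nc + p_in, "IN", "DI"))
    return pd.DataFrame(
        {
            "outcome": pd.Categorical(outcome, categories=STATES),
            "high_risk": high,
            "female": 0.0,
            "age_decades": 0.0,
        }
    )
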