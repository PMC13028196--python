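import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import logm

from gldtraj import markov
from gldtraj.config import MarkovConfig


def valid_q():
    return np.array([[-0.10, 0.06, 0.04],
                     [0.50, -0.60, 0.10],
                     [0.45, 0.15, -0.60]])


def taylor_expm(a, terms=60):
    """Independent series evaluation of the matrix exponential."""
    out = np.eye(a.shape[0])
    term = np.eye(a.shape[0])
    for k in range(1, terms):
        term = term @ a / k
        out = out + term
    return out


class TestTransitionProbability:
    def test_zero_generator_gives_identity(self):
        pm = markov.transition_probability(np.zeros((3, 3)), 1.0)
        assert np.allclose(pm.p, np.eye(3))

    def test_rows_sum_to_one(self):
        pm = markov.transition_probability(valid_q(), 1.0)
        assert np.max(np.abs(pm.p.sum(axis=1) - 1.0)) < 1e-10
        assert np.all(pm.p >= 0)

    def test_two_state_closed_form(self):
        """Embedded 2-state chain with q01=q10=lambda: P00(t)=(1+e^{-2 l t})/2."""
        lam, t = 0.5, 1.0
        q = np.array([[-lam, lam, 0.0], [lam, -lam, 0.0], [0.0, 0.0, 0.0]])
        pm = markov.transition_probability(q, t)
        expected = (1 + math.exp(-2 * lam * t)) / 2
        assert abs(pm.p[0, 0] - expected) < 1e-8
        assert np.allclose(pm.p, taylor_expm(q * t), atol=1e-10)

    def test_invalid_generator_rejected(self):
        q = valid_q()
        q[0, 1] = -0.1
        q[0, 0] = -q[0, 1:].sum()
        with pytest.raises(ValueError, match="non-negative"):
            markov.transition_probability(q, 1.0)

    def test_chapman_kolmogorov_within_piece(self):
        q = valid_q()
        half = markov.transition_probability(q, 0.5).p
        full = markov.transition_probability(q, 1.0).p
        assert np.max(np.abs(half @ half - full)) < 1e-8


class TestLogLikelihood:
    def toy_panel(self):
        return pd.DataFrame(
            {"y1": ["NC", "IN", "DI"], "y2": ["NC", "NC", "IN"],
             "y3": ["IN", "NC", "NC"]}
        )

    def test_single_nc_transition_zero_generator(self):
        panel = pd.DataFrame({"y1": ["NC"], "y2": ["NC"]})
        assert markov.log_likelihood(panel, [np.zeros((3, 3))]) == 0.0

    def test_zero_probability_transition_reports_minus_inf(self):
        panel = pd.DataFrame({"y1": ["NC"], "y2": ["IN"]})
        with pytest.warns(UserWarning):
            ll = markov.log_likelihood(panel, [np.zeros((3, 3))])
        assert ll == -np.inf

    def test_matches_brute_force_product(self):
        """Sum of log expm entries computed densely, patient by patient."""
        panel = self.toy_panel()
        qs = [valid_q(), 0.5 * valid_q()]
        got = markov.log_likelihood(panel, qs)
        sidx = {"NC": 0, "IN": 1, "DI": 2}
        expected = 0.0
        for _, row in panel.iterrows():
            seq = [sidx[row[c]] for c in ("y1", "y2", "y3")]
            for k in range(2):
                p = taylor_expm(qs[k])
                expected += math.log(p[seq[k], seq[k + 1]])
        assert abs(got - expected) < 1e-9

    def test_invariant_to_patient_order(self):
        panel = self.toy_panel()
        shuffled = panel.sample(frac=1.0, random_state=1)
        qs = [valid_q(), valid_q()]
        assert markov.log_likelihood(panel, qs) == pytest.approx(
            markov.log_likelihood(shuffled, qs)
        )

    def test_generator_count_mismatch(self):
        with pytest.raises(ValueError, match="generator"):
            markov.log_likelihood(self.toy_panel(), [valid_q()])


class TestFit:
    def test_saturation_on_embeddable_counts(self):
        p0 = np.array([[0.90, 0.06, 0.04], [0.50, 0.40, 0.10],
                       [0.45, 0.15, 0.40]])
        assert np.all(logm(p0)[~np.eye(3, dtype=bool)] > 0)  # embeddable
        counts = np.round(p0 * np.array([[20000.0], [2000.0], [1200.0]]))
        pf = markov.fit_piece(counts)
        p_emp = counts / counts.sum(axis=1, keepdims=True)
        p_hat = markov.transition_probability(pf.q).p
        assert np.max(np.abs(p_hat - p_emp)) < 1e-4

    def test_all_nc_panel_degenerates_to_identity(self):
        panel = pd.DataFrame({f"y{k}": ["NC"] * 50 for k in range(1, 6)})
        with pytest.warns(UserWarning, match="degenerate"):
            fit = markov.fit(panel, compute_ci=False)
        for pm in fit.probabilities:
            assert pm.p[0, 0] > 0.999

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        p_true = [markov.transition_probability(valid_q()).p] * 2
        panel = markov.simulate_panel(rng, 2000, [0.8, 0.1, 0.1], p_true)
        fit = markov.fit(panel, MarkovConfig(bootstrap_draws=200, seed=8))
        for pm in fit.probabilities:
            assert np.all(pm.ci_low <= pm.p + 1e-12)
            assert np.all(pm.ci_high >= pm.p - 1e-12)

    def test_delta_method_ci(self):
        rng = np.random.default_rng(4)
        p_true = [markov.transition_probability(valid_q()).p]
        panel = markov.simulate_panel(rng, 2000, [0.8, 0.1, 0.1], p_true)
        fit = markov.fit(panel, MarkovConfig(ci_method="delta", seed=8))
        pm = fit.probabilities[0]
        assert np.all(pm.ci_low <= pm.p) and np.all(pm.p <= pm.ci_high)

    def test_state_label_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        p_true = [markov.transition_probability(valid_q()).p]
        panel = markov.simulate_panel(rng, 3000, [0.6, 0.25, 0.15], p_true)
        fit = markov.fit(panel, compute_ci=False)
        perm = {"NC": "DI", "IN": "NC", "DI": "IN"}  # relabel states
        panel2 = panel.apply(lambda c: c.map(perm))
        fit2 = markov.fit(panel2, compute_ci=False)
        order = [markov.STATES.index(perm[s]) for s in markov.STATES]
        p2_back = fit2.probabilities[0].p[np.ix_(order, order)]
        assert np.max(np.abs(p2_back - fit.probabilities[0].p)) < 1e-5

    def test_fit_loglik_at_least_crude_start(self):
        counts = np.array([[800.0, 60.0, 40.0], [50.0, 30.0, 20.0],
                           [40.0, 10.0, 50.0]])
        pf = markov.fit_piece(counts)
        ll0 = markov.piece_loglik(markov._init_theta(counts), counts)
        assert pf.loglik >= ll0 - 1e-9


class TestGoodnessOfFit:
    def test_expected_row_sums_match_observed(self):
        rng = np.random.default_rng(2)
        p_true = [markov.transition_probability(valid_q()).p] * 2
        panel = markov.simulate_panel(rng, 1500, [0.7, 0.2, 0.1], p_true)
        fit = markov.fit(panel, compute_ci=False)
        gof = markov.goodness_of_fit(panel, fit)
        per = gof.groupby(["interval_index", "from_state"])[
            ["observed", "expected"]].sum()
        assert np.allclose(per["observed"], per["expected"], atol=1e-8)

    def test_saturated_fit_residuals_near_zero(self):
        p0 = np.array([[0.90, 0.06, 0.04], [0.50, 0.40, 0.10],
                       [0.45, 0.15, 0.40]])
        counts = np.round(p0 * np.array([[20000.0], [2000.0], [1200.0]]))
        fit = markov.fit([counts], compute_ci=False)
        gof = markov.goodness_of_fit([counts], fit)
        assert gof["pearson_residual"].abs().max() < 0.02

    def test_toy_hand_check(self):
        counts = np.array([[2.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        fit = markov.fit([counts], compute_ci=False)
        gof = markov.goodness_of_fit([counts], fit).set_index(
            ["from_state", "to_state"]
        )
        assert gof.loc[("NC", "NC"), "observed"] == 2.0
        assert gof.loc[("DI", "DI"), "observed"] == 1.0
        assert abs(gof.loc[("NC", "NC"), "expected"] - 2.0) < 1e-3
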