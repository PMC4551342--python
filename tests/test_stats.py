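import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ctdna_monitor as cm
from ctdna_monitor.stats import aic_firth, default_transforms


class TestClopperPearson:
    def test_all_successes_one_sided_closed_form(self):
        ci = cm.clopper_pearson(6, 6, sidedness="one_sided_lower")
        assert ci.lower == pytest.approx(0.05 ** (1 / 6), rel=1e-9)
        assert ci.upper == 1.0
        assert round(100 * ci.lower) == 61

    def test_thirteen_of_fourteen_two_sided(self):
        ci = cm.clopper_pearson(13, 14)
        assert ci.lower == pytest.approx(0.6613, abs=2e-4)
        assert ci.upper == pytest.approx(0.9982, abs=2e-4)
        assert round(100 * ci.lower) == 66

    def test_boundaries(self):
        assert cm.clopper_pearson(0, 10).lower == 0.0
        assert cm.clopper_pearson(10, 10).upper == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cm.clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            cm.clopper_pearson(1, 2, sidedness="sideways")

    def test_conservative_coverage_at_nominal_level(self):
        """Exactness guarantees >= 95% empirical coverage."""
        rng = np.random.default_rng(0)
        n, reps = 20, 2_000
        for p in (0.1, 0.5, 0.9):
            xs = rng.binomial(n, p, size=reps)
            covered = 0
            cis = {x: cm.clopper_pearson(int(x), n) for x in np.unique(xs)}
            for x in xs:
                ci = cis[int(x)]
                covered += ci.lower <= p <= ci.upper
            assert covered / reps >= 0.95


class TestMannWhitney:
    def test_disjoint_samples_exact_p(self):
        U, p = cm.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = cm.mann_whitney_u([1, 2, 3], [1, 2, 3], exact=False)
        assert p == pytest.approx(1.0)

    def test_two_sided_symmetry(self):
        a, b = [1.2, 3.4, 2.2, 5.0], [0.5, 4.4, 6.1]
        _, p_ab = cm.mann_whitney_u(a, b)
        _, p_ba = cm.mann_whitney_u(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_exact_close_to_asymptotic_at_n10(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 10)
        _, p_exact = cm.mann_whitney_u(a, b, exact=True)
        _, p_asym = cm.mann_whitney_u(a, b, exact=False)
        assert abs(p_exact - p_asym) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cm.mann_whitney_u([], [1.0])


class TestFirthLogistic:
    def test_complete_separation_matches_add_half_closed_form(self):
        """On a 2x2 table the Firth fit equals adding 1/2 to each cell."""
        y = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([0.0, 0, 0, 1, 1, 1])
        fit = cm.firth_logistic(y, x[:, None])
        assert fit.converged
        assert fit.coef[1] == pytest.approx(math.log(49.0), abs=1e-6)
        assert fit.odds_ratios[1] == pytest.approx(49.0, abs=1e-4)

    def test_two_by_two_equivalence_general_counts(self):
        # cells: x=0 -> 5 neg, 2 pos; x=1 -> 1 neg, 6 pos
        y = np.array([0] * 5 + [1] * 2 + [0] * 1 + [1] * 6)
        x = np.array([0.0] * 7 + [1.0] * 7)
        fit = cm.firth_logistic(y, x[:, None])
        expect = math.log((6.5 * 5.5) / (1.5 * 2.5))
        assert fit.coef[1] == pytest.approx(expect, abs=1e-6)

    def test_brute_force_grid_cross_check(self):
        """Newton optimum matches direct maximization of the penalized
        log-likelihood on a coefficient grid."""
        y = np.array([0, 0, 1, 0, 1, 1, 1])
        x = np.array([-1.2, 0.1, 0.3, 0.8, 1.1, 1.9, 2.5])
        X = np.column_stack([np.ones(7), x])

        def pen_ll(b0, b1):
            eta = X @ np.array([b0, b1])
            pi = 1 / (1 + np.exp(-eta))
            w = pi * (1 - pi)
            info = (X.T * w) @ X
            sign, logdet = np.linalg.slogdet(info)
            if sign <= 0:
                return -np.inf
            return float(np.sum(y * eta - np.log1p(np.exp(eta)))) + 0.5 * logdet

        fit = cm.firth_logistic(y, x[:, None])
        grid = np.linspace(-3, 3, 121)
        best = max(((b0, b1) for b0 in grid for b1 in grid), key=lambda t: pen_ll(*t))
        assert fit.coef[0] == pytest.approx(best[0], abs=0.06)
        assert fit.coef[1] == pytest.approx(best[1], abs=0.06)
        assert fit.loglik_penalized >= pen_ll(*best) - 1e-9

    def test_balanced_table_zero_slope(self):
        fit = cm.firth_logistic([0, 1, 0, 1], np.array([0.0, 0, 1, 1])[:, None])
        assert fit.coef[1] == pytest.approx(0.0, abs=1e-8)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_finite_estimates_under_random_separation(self, seed):
        """Separated datasets keep finite coefficients (n <= 50)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        cut = rng.normal()
        x = rng.normal(size=n)
        y = (x > cut).astype(int)
        if y.min() == y.max():
            return
        fit = cm.firth_logistic(y, x[:, None])
        assert np.all(np.isfinite(fit.coef))
        assert np.all(np.isfinite(fit.se))

    def test_parameter_recovery_on_continuous_covariate(self):
        rng = np.random.default_rng(2)
        est = []
        for _ in range(60):
            x = rng.normal(size=200)
            eta = 0.3 + 1.0 * x
            y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(int)
            est.append(cm.firth_logistic(y, x[:, None]).coef[1])
        assert np.mean(est) == pytest.approx(1.0, abs=0.1)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="rank"):
            cm.firth_logistic([0, 1, 0, 1, 0, 1], X)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cm.firth_logistic([1, 1, 1], np.arange(3.0)[:, None])

    def test_profile_ci_contains_estimate_and_can_be_infinite(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([0.0, 0, 0, 1, 1, 1])
        fit = cm.firth_logistic(y, x[:, None], profile_ci_level=0.95)
        lo, hi = fit.profile_ci[1]
        assert lo < fit.coef[1]
        assert hi > fit.coef[1] or math.isinf(hi)


class TestTransformSelection:
    def test_log2_selected_when_risk_is_log2_linear(self):
        hits = 0
        for seed in range(40):
            pct, y = cm.simulate_outcome_covariates(200, 2.0, seed=seed)
            best, _ = cm.select_transform(pct, {"recurrence": y})
            hits += best.name == "log2"
        assert hits >= 32  # >= 80%

    def test_single_candidate_returned_unconditionally(self):
        pct, y = cm.simulate_outcome_covariates(100, 2.0, seed=5)
        only = default_transforms()[0]
        best, sums = cm.select_transform(pct, {"recurrence": y}, [only])
        assert best is only and set(sums) == {"identity"}

    def test_identical_candidates_tie_breaks_to_first(self):
        pct, y = cm.simulate_outcome_covariates(100, 2.0, seed=6)
        c1 = cm.CovariateTransform("log2_a", np.log2, floor=0.01)
        c2 = cm.CovariateTransform("log2_b", np.log2, floor=0.01)
        best, _ = cm.select_transform(pct, {"recurrence": y}, [c1, c2])
        assert best is c1

    def test_aic_uses_penalized_loglik(self):
        pct, y = cm.simulate_outcome_covariates(100, 2.0, seed=7)
        x = np.log2(np.maximum(pct, 0.01))
        fit = cm.firth_logistic(y, x[:, None])
        assert aic_firth(fit) == pytest.approx(-2 * fit.loglik_penalized + 4)


class _Rec:
    def __init__(self, pid, samples, recurrence, last_fu=120.0):
        self.patient_id = pid
        self.samples = samples
        self.time_to_recurrence = recurrence
        self.time_to_last_followup = last_fu


class _Pt:
    def __init__(self, t, pct):
        self.time_months = t
        self.ctdna_percent = pct


class TestCtdnaCovariate:
    def test_most_recent_pre_event_sample_used(self):
        rec = _Rec("p1", [_Pt(12.0, 2.0), _Pt(24.0, 8.0)], recurrence=30.0)
        out = cm.ctdna_covariate([rec], "time_to_recurrence")
        assert out["p1"] == pytest.approx(3.0)  # log2(8)

    def test_zero_percent_floored_before_log(self):
        rec = _Rec("p1", [_Pt(12.0, 0.0)], recurrence=30.0)
        out = cm.ctdna_covariate([rec], "time_to_recurrence", floor=0.01)
        assert out["p1"] == pytest.approx(math.log2(0.01))

    def test_doubling_percent_adds_one(self):
        r1 = _Rec("a", [_Pt(12.0, 4.0)], recurrence=30.0)
        r2 = _Rec("b", [_Pt(12.0, 8.0)], recurrence=30.0)
        out = cm.ctdna_covariate([r1, r2], "time_to_recurrence")
        assert out["b"] - out["a"] == pytest.approx(1.0)

    def test_patient_without_eligible_sample_omitted(self):
        rec = _Rec("p1", [_Pt(40.0, 5.0)], recurrence=30.0)
        assert cm.ctdna_covariate([rec], "time_to_recurrence") == {}

    def test_censoring_time_used_when_no_event(self):
        rec = _Rec("p1", [_Pt(12.0, 1.0)], recurrence=None, last_fu=100.0)
        out = cm.ctdna_covariate([rec], "time_to_recurrence")
        assert out["p1"] == pytest.approx(0.0)  # log2(1)
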