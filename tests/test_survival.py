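"""Cox fitting, signature construction, risk scores, binning, KM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from tsmir.containers import CoxFit, RiskScores, Signature
from tsmir.simulate import default_survival_truth, gen_survival_cohort
from tsmir.survival import (
    bin_risk_levels,
    breslow_partial_loglik,
    build_signature,
    compute_risk_scores,
    cox_screen,
    km_curves,
    survival_association,
    univariate_cox,
)

from .conftest import make_expr, make_survival


def brute_force_cox(x, time, event, bound=8.0):
    """Independent oracle: hand-written Breslow partial likelihood
    maximized by bounded golden-section search."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)

    def neg_loglik(beta):
        ll = 0.0
        for i in range(len(x)):
            if event[i] != 1:
                continue
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    res = minimize_scalar(neg_loglik, bounds=(-bound, bound), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


class TestUnivariateCox:
    def test_toy_matches_brute_force_oracle(self):
        # interleaved groups: finite maximum of the partial likelihood
        times = np.arange(1.0, 9.0)
        x = np.array([0, 1, 0, 1, 0, 1, 0, 1], float)
        st_tab = make_survival(times, np.ones(8, int))
        fit = univariate_cox(x, st_tab)
        assert fit.coef == pytest.approx(brute_force_cox(x, times, st_tab.event),
                                         abs=1e-4)

    def test_random_small_cohorts_match_oracle(self):
        """Oracle equivalence on <=10-sample cohorts (with ties and
        censoring) within 1e-4."""
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            x = rng.standard_normal(n).round(1)
            time = rng.integers(1, 6, size=n).astype(float)  # forces ties
            event = rng.integers(0, 2, size=n)
            if event.sum() < 2 or np.ptp(x) == 0:
                continue
            surv = make_survival(time, event)
            fit = univariate_cox(x, surv)
            if not fit.converged or abs(fit.coef) > 6:
                continue  # monotone-likelihood draw: no finite MLE
            assert fit.coef == pytest.approx(
                brute_force_cox(x, time, event), abs=1e-4
            )

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(30)
        surv = make_survival(rng.exponential(1, 30), np.ones(30, int))
        assert univariate_cox(x, surv).coef == pytest.approx(
            -univariate_cox(-x, surv).coef, abs=1e-9
        )

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(21)
        n = 80
        x = rng.standard_normal(n)
        time = rng.exponential(1.0 / np.exp(0.5 * x))
        event = (rng.random(n) < 0.7).astype(int)
        surv = make_survival(time, event)
        fit = univariate_cox(x, surv)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": time, "e": event, "x": x}), "t", "e"
        )
        assert fit.coef == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(4)
        n = 400
        x = rng.standard_normal(n)
        surv = make_survival(rng.exponential(1, n), np.ones(n, int))
        fit = univariate_cox(x, surv)
        assert fit.ci_low < 1.0 < fit.ci_high

    def test_separable_covariate_warns_not_converged(self):
        # all short survivors in one group: monotone partial likelihood
        times = np.arange(1.0, 9.0)
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = univariate_cox(x, make_survival(times, np.ones(8, int)))
        assert not fit.converged

    def test_degenerate_inputs_rejected(self):
        surv = make_survival([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            univariate_cox(np.ones(3), surv)
        no_events = make_survival([1.0, 2.0, 3.0], [0, 0, 1])
        with pytest.raises(ValueError, match="events"):
            univariate_cox(np.array([1.0, 2.0, 3.0]), no_events)


class TestBuildSignature:
    def test_rule_application(self):
        fits = {
            "A": CoxFit(0.2, 0.05, 0.01, 100, 80),
            "B": CoxFit(-0.3, 0.1, 0.04, 100, 80),
            "C": CoxFit(0.5, 0.4, 0.2, 100, 80),
        }
        sig = build_signature(fits, alpha=0.05)
        assert sig.c_plus == ["A"] and sig.c_minus == ["B"]

    def test_alpha_zero_empty(self):
        fits = {"A": CoxFit(0.2, 0.05, 0.001, 100, 80)}
        sig = build_signature(fits, alpha=0.0)
        assert len(sig) == 0

    def test_zero_coefficient_dropped_with_warning(self):
        fits = {"A": CoxFit(0.0, 0.05, 0.01, 100, 80)}
        with pytest.warns(RuntimeWarning, match="zero coefficient"):
            sig = build_signature(fits, alpha=0.05)
        assert len(sig) == 0

    def test_planted_sign_recovery_over_seeds(self):
        agree = total = 0
        for seed in range(20):
            expr, surv, truth = gen_survival_cohort(n_samples=1000, seed=seed)
            fits = cox_screen(expr, surv)
            for g in truth.planted_cpos:
                agree += fits[g].coef > 0
            for g in truth.planted_cneg:
                agree += fits[g].coef < 0
            total += len(truth.planted_cpos) + len(truth.planted_cneg)
        assert agree / total >= 0.90


class TestRiskScores:
    def _expr_one_sample(self, cp_vals, cm_vals):
        genes = [f"P{i}" for i in range(len(cp_vals))] + [
            f"M{i}" for i in range(len(cm_vals))
        ]
        expr = make_expr(
            np.array(list(cp_vals) + list(cm_vals), float).reshape(-1, 1),
            feature_ids=genes, log2=True,
        )
        sig = Signature([f"P{i}" for i in range(len(cp_vals))],
                        [f"M{i}" for i in range(len(cm_vals))])
        return expr, sig

    def test_hand_medians(self):
        expr, sig = self._expr_one_sample((2, 4, 6), (1, 3))
        rs = compute_risk_scores(expr, sig)
        assert rs.table["u"].iloc[0] == 4.0
        assert rs.table["d"].iloc[0] == 2.0
        assert rs.rs[0] == 2.0

    def test_all_equal_gives_zero(self):
        expr, sig = self._expr_one_sample((5, 5, 5), (5, 5))
        assert compute_risk_scores(expr, sig).rs[0] == 0.0

    def test_translation_equivariance_and_permutation_invariance(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((9, 12))
        genes = [f"G{i}" for i in range(9)]
        expr = make_expr(vals, feature_ids=genes, log2=True)
        sig = Signature(genes[:5], genes[5:])
        base = compute_risk_scores(expr, sig).rs
        # add a constant to every C+ gene of every sample
        shifted = vals.copy()
        shifted[:5] += 1.25
        rs_shift = compute_risk_scores(
            make_expr(shifted, feature_ids=genes, log2=True), sig
        ).rs
        np.testing.assert_allclose(rs_shift, base + 1.25, atol=1e-12)
        # shuffling gene order within groups changes nothing
        perm = Signature(genes[:5][::-1], genes[5:][::-1])
        np.testing.assert_allclose(compute_risk_scores(expr, perm).rs, base)

    def test_missing_genes_dropped_and_empty_group_warns(self):
        expr, sig = self._expr_one_sample((2, 4, 6), (1, 3))
        bigger = Signature(sig.c_plus + ["ABSENT"], sig.c_minus)
        rs = compute_risk_scores(expr, bigger, missing="drop")
        assert rs.table["u"].iloc[0] == 4.0
        with pytest.raises(KeyError):
            compute_risk_scores(expr, bigger, missing="raise")
        only_plus = Signature(sig.c_plus, ["GONE"])
        with pytest.warns(RuntimeWarning, match="median set to 0"):
            rs2 = compute_risk_scores(expr, only_plus, missing="drop")
        assert rs2.rs[0] == 4.0

    def test_empty_signature_error(self):
        expr, _ = self._expr_one_sample((1, 2), (3,))
        with pytest.raises(ValueError):
            compute_risk_scores(expr, Signature([], []))


def _scores(rs_values):
    rs = np.asarray(rs_values, float)
    tab = pd.DataFrame(
        {"u": rs, "d": 0.0, "rs": rs},
        index=pd.Index([f"s{i}" for i in range(len(rs))], name="sample_id"),
    )
    return RiskScores(tab)


class TestBinRiskLevels:
    def test_equal_width_assignment(self):
        # range [0, 3], 4 levels of width 0.75
        binned = bin_risk_levels(_scores([0.0, 1.0, 2.0, 3.0]), 4)
        np.testing.assert_array_equal(binned.levels, [1, 2, 3, 4])

    def test_max_always_in_last_level(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            rs = rng.standard_normal(25)
            binned = bin_risk_levels(_scores(rs), 4)
            assert binned.levels[np.argmax(rs)] == 4
            assert binned.levels.min() >= 1 and binned.levels.max() <= 4

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        rs = rng.standard_normal(40)
        base = bin_risk_levels(_scores(rs), 4).levels
        trans = bin_risk_levels(_scores(2.5 * rs - 7.0), 4).levels
        np.testing.assert_array_equal(base, trans)

    def test_degenerate_constant_scores(self):
        with pytest.warns(RuntimeWarning, match="identical"):
            binned = bin_risk_levels(_scores([1.0, 1.0, 1.0]), 4)
        assert set(binned.levels) == {1}

    def test_invalid_level_count(self):
        with pytest.raises(ValueError):
            bin_risk_levels(_scores([0.0, 1.0]), 1)


class TestSurvivalAssociation:
    def test_toy_levels_match_brute_force(self):
        levels = np.array([1, 1, 2, 2, 3, 3, 4, 4], float)
        times = np.array([3.0, 8.0, 2.0, 6.0, 1.0, 5.0, 4.0, 7.0])
        surv = make_survival(times, np.ones(8, int))
        fit = survival_association(levels, surv)
        assert fit.coef == pytest.approx(
            brute_force_cox(levels, times, surv.event), abs=1e-4
        )

    def test_null_levels_hr_near_one(self):
        rng = np.random.default_rng(3)
        n = 500
        levels = rng.integers(1, 5, n).astype(float)
        surv = make_survival(rng.exponential(1, n), np.ones(n, int))
        fit = survival_association(levels, surv)
        assert fit.ci_low < 1.0 < fit.ci_high

    def test_requires_two_levels(self):
        surv = make_survival([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            survival_association(np.array([2, 2]), surv)

    def test_pipeline_hr_tracks_oracle_on_true_rs(self):
        """Estimated per-level log HR from the fitted signature within
        25% of a Cox fit on levels derived from the true risk score."""
        ratios = []
        for seed in range(10):
            expr, surv, truth = gen_survival_cohort(n_samples=1000, seed=seed)
            sig = build_signature(cox_screen(expr, surv), 0.05)
            est = survival_association(
                bin_risk_levels(compute_risk_scores(expr, sig), 4).levels, surv
            )
            true_sig = Signature(list(truth.planted_cpos),
                                 list(truth.planted_cneg))
            oracle = survival_association(
                bin_risk_levels(compute_risk_scores(expr, true_sig), 4).levels,
                surv,
            )
            ratios.append(est.coef / oracle.coef)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.25)

    def test_end_to_end_positive_association(self):
        hits = 0
        for seed in range(20):
            expr, surv, _ = gen_survival_cohort(n_samples=1000, seed=100 + seed)
            sig = build_signature(cox_screen(expr, surv), 0.05)
            fit = survival_association(
                bin_risk_levels(compute_risk_scores(expr, sig), 4).levels, surv
            )
            hits += fit.coef > 0 and fit.p < 0.01
        assert hits >= 19  # >= 95% of seeds

    def test_null_calibration_with_fixed_signature(self):
        """Type-I error of the association test at nominal 0.05 stays
        below 0.07 when the signature is fixed a priori (beta_rs = 0)."""
        truth = default_survival_truth(beta_rs=0.0)
        sig = Signature(list(truth.planted_cpos), list(truth.planted_cneg))
        rejections = 0
        n_cohorts = 200
        for seed in range(n_cohorts):
            expr, surv, _ = gen_survival_cohort(
                n_samples=200, truth=truth, seed=seed
            )
            fit = survival_association(
                bin_risk_levels(compute_risk_scores(expr, sig), 4).levels, surv
            )
            rejections += fit.p < 0.05
        assert rejections / n_cohorts <= 0.07


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        surv = make_survival([1.0, 2.0, 3.0], [1, 1, 1])
        curve = km_curves(np.ones(3, int), surv)[1]
        lookup = dict(zip(curve["time"], curve["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_censoring_reduces_risk_set(self):
        # times 1(c), 2(e), 3(e): S(2) = 1/2, S(3) = 0
        surv = make_survival([1.0, 2.0, 3.0], [0, 1, 1])
        curve = km_curves(np.ones(3, int), surv)[1]
        lookup = dict(zip(curve["time"], curve["survival"]))
        assert lookup[2.0] == pytest.approx(0.5)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_one(self):
        surv = make_survival([1.0, 2.0, 3.0], [0, 0, 0])
        curve = km_curves(np.ones(3, int), surv)[1]
        assert (curve["survival"] == 1.0).all()

    @given(st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_nonincreasing_starting_at_one(self, data):
        n = data.draw(st.integers(2, 15))
        times = data.draw(
            st.lists(st.floats(0.1, 50, allow_nan=False), min_size=n,
                     max_size=n)
        )
        events = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        levels = np.array(
            data.draw(st.lists(st.integers(1, 2), min_size=n, max_size=n))
        )
        curves = km_curves(levels, make_survival(times, events))
        for curve in curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()
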