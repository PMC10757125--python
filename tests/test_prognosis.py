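"""Cox fitting, risk stratification, Kaplan-Meier, log-rank, hazard ratios."""

import numpy as np
import pandas as pd
import pytest

from diffconet import prognosis, synthetic_data as sd
from diffconet.io import SurvivalTable, ValidationError
from diffconet.prognosis import (
    ConvergenceError,
    SeparationError,
    fit_cox,
    group_hazard_ratio,
    km_estimate,
    logrank_test,
    prognostic_index,
    stratify,
)


def _survival(times, events, samples=None):
    samples = samples or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(
        data=pd.DataFrame({"time": times, "event": events},
                          index=pd.Index(samples, name="sample_id"))
    )


FOUR_SUBJECT = _survival([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], list("abcd"))
FOUR_COV = pd.DataFrame({"z": [1.0, 0.0, 1.0, 0.0]}, index=list("abcd"))


class TestFitCox:
    def test_four_subject_fixture_matches_grid_oracle(self, cox_grid_oracle):
        model = fit_cox(FOUR_SUBJECT, FOUR_COV, zscore=False)
        oracle = cox_grid_oracle(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 1, 1]),
            np.array([1.0, 0.0, 1.0, 0.0]),
        )
        assert abs(model.beta[0] - oracle) < 1e-4
        # analytic check: u = e^beta solves u^2 - u - 4 = 0
        u = np.exp(model.beta[0])
        assert u**2 - u - 4 == pytest.approx(0.0, abs=1e-7)
        assert model.beta[0] == pytest.approx(0.9406136, abs=1e-6)

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(0)
        n = 1000
        t = rng.exponential(1.0, n)
        x = rng.normal(size=n)
        surv = _survival(t, np.ones(n, int))
        model = fit_cox(surv, pd.DataFrame({"x": x}, index=surv.data.index))
        assert abs(model.beta[0]) < 0.1

    def test_separation_detected_and_named(self):
        surv = _survival([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], list("abcd"))
        cov = pd.DataFrame({"sepgene": [1.0, 1.0, 0.0, 0.0]}, index=list("abcd"))
        with pytest.raises(SeparationError, match="sepgene"):
            fit_cox(surv, cov, zscore=False)

    def test_constant_covariate_rejected(self):
        cov = pd.DataFrame({"c": [1.0, 1.0, 1.0, 1.0]}, index=list("abcd"))
        with pytest.raises(ValidationError, match="constant"):
            fit_cox(FOUR_SUBJECT, cov)

    def test_fewer_than_two_events_rejected(self):
        surv = _survival([1.0, 2.0, 3.0], [1, 0, 0], list("abc"))
        cov = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=list("abc"))
        with pytest.raises(ValidationError):
            fit_cox(surv, cov)

    def test_matches_lifelines_on_random_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(42)
        n = 150
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        t = rng.exponential(np.exp(-(0.5 * x1 - 0.3 * x2)))
        c = rng.exponential(3.0, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        surv = _survival(time, event)
        cov = pd.DataFrame({"x1": x1, "x2": x2}, index=surv.data.index)
        model = fit_cox(surv, cov, zscore=False, ties="efron")
        df = pd.DataFrame({"T": time, "E": event, "x1": x1, "x2": x2})
        ref = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(model.beta, ref.params_.to_numpy(), atol=1e-6)
        assert np.allclose(
            np.sqrt(np.diag(model.cov)), ref.standard_errors_.to_numpy(),
            atol=1e-6,
        )

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(7)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.4 * x))  # continuous: no ties
        surv = _survival(t, np.ones(n, int))
        cov = pd.DataFrame({"x": x}, index=surv.data.index)
        b1 = fit_cox(surv, cov, ties="efron").beta[0]
        b2 = fit_cox(surv, cov, ties="breslow").beta[0]
        assert b1 == pytest.approx(b2, abs=1e-9)


class TestPrognosticIndex:
    def test_zero_coefficients_give_zero_index(self):
        model = fit_cox(FOUR_SUBJECT, FOUR_COV, zscore=False)
        model.beta = np.zeros_like(model.beta)
        pi = prognostic_index(model, FOUR_COV)
        assert (pi == 0).all()

    def test_linear_arithmetic(self):
        model = fit_cox(FOUR_SUBJECT, FOUR_COV, zscore=False)
        model.beta = np.array([0.5])
        pi = prognostic_index(model, pd.DataFrame({"z": [2.0]}, index=["s"]))
        assert pi.iloc[0] == pytest.approx(1.0)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(3)
        n = 50
        cov = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"],
                           index=[f"s{i}" for i in range(n)])
        surv = _survival(rng.exponential(1, n), np.ones(n, int),
                         list(cov.index))
        model = fit_cox(surv, cov)
        pi1 = prognostic_index(model, cov)
        pi2 = prognostic_index(model, cov[["c", "a", "b"]])
        assert np.allclose(pi1, pi2)

    def test_missing_gene_rejected(self):
        model = fit_cox(FOUR_SUBJECT, FOUR_COV, zscore=False)
        with pytest.raises(ValidationError):
            prognostic_index(model, pd.DataFrame({"other": [1.0]}, index=["s"]))


class TestStratify:
    def test_median_split(self):
        pi = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups = stratify(pi, "median")
        assert groups.samples("low") == ["a", "b"]
        assert groups.samples("high") == ["c", "d"]

    def test_ties_go_to_low(self):
        pi = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        groups = stratify(pi, "median")
        assert groups.samples("low") == ["a", "b", "c"]
        assert groups.samples("high") == ["d"]

    def test_identical_indices_rejected(self):
        with pytest.raises(ValidationError):
            stratify(pd.Series([1.0, 1.0, 1.0]), "median")

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        pi = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        a = stratify(pi, "median").labels
        b = stratify(np.exp(pi), "median").labels
        assert a.equals(b)

    def test_optimal_split_beats_median(self):
        rng = np.random.default_rng(5)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-np.log(2) * x))
        surv = _survival(t, np.ones(n, int))
        pi = pd.Series(x, index=surv.data.index)

        def stat_of(groups):
            lo, hi = groups.samples("low"), groups.samples("high")
            return logrank_test(
                surv.data.loc[lo, "time"].to_numpy(),
                surv.data.loc[lo, "event"].to_numpy(),
                surv.data.loc[hi, "time"].to_numpy(),
                surv.data.loc[hi, "event"].to_numpy(),
            )[0]

        s_med = stat_of(stratify(pi, "median"))
        s_opt = stat_of(stratify(pi, "optimal", survival=surv))
        assert s_opt >= s_med


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        km = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
        assert np.allclose(km.survival, 1.0)

    def test_hand_product_limit(self):
        # event at 1 (3 at risk), censored at 2, event at 3 (1 at risk):
        # S(1) = 2/3, S(3) = 2/3 * 0 = 0
        km = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        assert km.survival.tolist() == pytest.approx([2 / 3, 2 / 3, 0.0])
        assert km.at_risk.tolist() == [3, 2, 1]

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1.0, 200)
        km = km_estimate(t, np.ones(200, int))
        empirical = [(t > ti).mean() for ti in km.times]
        assert np.allclose(km.survival, empirical, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate(np.array([]), np.array([]))


class TestLogrank:
    def test_hand_computed_statistic(self):
        # events X at 1,2 and Y at 3,4: O_X=2, E_X=5/6, V=17/36 -> 49/17
        stat, p = logrank_test(
            np.array([1.0, 2.0]), np.array([1, 1]),
            np.array([3.0, 4.0]), np.array([1, 1]),
        )
        assert stat == pytest.approx(49 / 17, rel=1e-9)
        assert p == pytest.approx(0.0896, abs=2e-4)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(9)
        ta, tb = rng.exponential(1, 30), rng.exponential(1.5, 40)
        ea, eb = np.ones(30, int), np.ones(40, int)
        s1, _ = logrank_test(ta, ea, tb, eb)
        s2, _ = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(np.array([1.0]), np.array([0]),
                         np.array([2.0]), np.array([0]))


class TestGroupHazardRatio:
    def test_four_subject_fixture(self):
        pi = pd.Series([1.0, 0.0, 1.0, 0.0], index=list("abcd"))
        groups = prognosis.RiskGroups(
            labels=pd.Series(["high", "low", "high", "low"], index=list("abcd")),
            method="manual", split_value=0.5,
        )
        hr = group_hazard_ratio(FOUR_SUBJECT, groups)
        assert hr.hr == pytest.approx(np.exp(0.9406136), rel=1e-4)

    def test_null_groups_hr_near_one(self):
        rng = np.random.default_rng(4)
        n = 1000
        t = rng.exponential(1.0, n)
        surv = _survival(t, np.ones(n, int))
        labels = pd.Series(
            np.where(np.arange(n) % 2 == 0, "high", "low"),
            index=surv.data.index,
        )
        groups = prognosis.RiskGroups(labels=labels, method="manual",
                                      split_value=0.0)
        hr = group_hazard_ratio(surv, groups)
        assert 0.8 <= hr.hr <= 1.25


class TestEvaluate:
    def _signal_bundle(self, seed=0):
        return sd.cohort_fixture(seed=seed)

    def test_full_module_result_structure(self):
        b = self._signal_bundle()
        res = prognosis.evaluate_network_prognosis(
            b.survival_expr, b.truth.hubs["PONO"], b.survival
        )
        s = res.summary()
        assert s["n_low"] >= 1 and s["n_high"] >= 1
        assert 0 <= s["logrank_p"] <= 1
        assert s["hazard_ratio"] > 1  # planted risk signal

    def test_subset_and_full_module_both_valid(self):
        # mirrors evaluating the positive-class-only genes vs the whole module
        b = self._signal_bundle()
        full = prognosis.evaluate_network_prognosis(
            b.survival_expr, b.truth.hubs["PONO"], b.survival
        )
        subset = prognosis.evaluate_network_prognosis(
            b.survival_expr, b.truth.hubs["PONO"][:3], b.survival
        )
        assert full.hazard_ratio.hr > 0 and subset.hazard_ratio.hr > 0

    def test_insample_recovers_designed_signal(self):
        b = self._signal_bundle(seed=11)
        res = prognosis.evaluate_network_prognosis(
            b.survival_expr, b.truth.hubs["PONO"], b.survival,
            pi_method="insample",
        )
        assert res.logrank_p < 1e-3
        assert res.hazard_ratio.hr > 1.5
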