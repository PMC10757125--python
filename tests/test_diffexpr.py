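"""Differential expression: moderated t, BH adjustment, DEG calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from diffconet import diffexpr
from diffconet.io import ExpressionDataset, PhenotypeTable, ValidationError


def _dataset(matrix, n_resp, n_non, genes=None):
    samples = [f"r{i}" for i in range(n_resp)] + [f"n{i}" for i in range(n_non)]
    genes = genes or [f"g{i}" for i in range(len(matrix))]
    ds = ExpressionDataset(
        values=pd.DataFrame(matrix, index=genes, columns=samples, dtype=float)
    )
    ph = PhenotypeTable(
        labels=pd.Series(
            ["response"] * n_resp + ["nonresponse"] * n_non, index=samples
        )
    )
    return ds, ph


class TestModeratedT:
    def test_identical_groups_give_null_statistics(self):
        ds, ph = _dataset([[2.0, 2.0, 2.0, 2.0, 2.0, 2.0]], 3, 3)
        rec = diffexpr.moderated_t_test(ds, ph, moderation=False)
        assert rec.loc["g0", "t_statistic"] == 0.0
        assert rec.loc["g0", "p_value"] == 1.0
        assert rec.loc["g0", "log2_fc"] == 0.0

    def test_pooled_t_closed_form(self):
        # A=(1,2,3), B=(3,4,5): pooled s2=1, se=sqrt(2/3), t=-2.449, df=4
        ds, ph = _dataset([[1, 2, 3, 3, 4, 5]], 3, 3)
        rec = diffexpr.moderated_t_test(ds, ph, moderation=False)
        assert rec.loc["g0", "log2_fc"] == pytest.approx(-2.0)
        assert rec.loc["g0", "t_statistic"] == pytest.approx(-2.449489742783178)
        assert rec.loc["g0", "p_value"] == pytest.approx(0.07048399691021993)

    def test_infinite_prior_pools_to_prior_variance(self):
        params = diffexpr.ModerationParams(
            prior_df=np.inf, prior_var=0.25, residual_df=4
        )
        sv = np.array([0.1, 1.0, 10.0])
        assert np.allclose(params.posterior_var(sv), 0.25)

    def test_zero_prior_df_is_ordinary_variance(self):
        params = diffexpr.ModerationParams(prior_df=0.0, prior_var=9.9, residual_df=4)
        sv = np.array([0.1, 1.0])
        assert np.allclose(params.posterior_var(sv), sv)

    def test_condition_with_single_sample_rejected(self):
        ds, ph = _dataset([[1, 2, 3, 4]], 1, 3)
        with pytest.raises(ValidationError):
            diffexpr.moderated_t_test(ds, ph)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_moderation_off_matches_pooled_t(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2, genes = 4, 6, 20
        x = rng.normal(7, 1, (genes, n1 + n2))
        ds, ph = _dataset(x, n1, n2)
        rec = diffexpr.moderated_t_test(ds, ph, moderation=False)
        t_ref, p_ref = stats.ttest_ind(
            x[:, :n1], x[:, n1:], axis=1, equal_var=True
        )
        assert np.allclose(rec["t_statistic"], t_ref, atol=1e-10)
        assert np.allclose(rec["p_value"], p_ref, atol=1e-10)

    def test_matches_reference_empirical_bayes_fit(self):
        # heteroscedastic fixture frozen against an independent
        # empirical-Bayes reference implementation (Bioconductor limma,
        # same fixture, run once): prior df 2.5891, prior var 0.16266
        rng = np.random.default_rng(11)
        n1, n2, G = 5, 7, 300
        sd_g = np.exp(rng.normal(-0.7, 0.6, G))
        x = np.hstack(
            [
                rng.normal(0, 1, (G, n1)) * sd_g[:, None] + 7,
                rng.normal(0, 1, (G, n2)) * sd_g[:, None] + 7,
            ]
        )
        ds, ph = _dataset(x, n1, n2)
        rec = diffexpr.moderated_t_test(ds, ph, moderation=True)
        m1 = x[:, :n1]
        m2 = x[:, n1:]
        s2 = (
            ((m1 - m1.mean(1, keepdims=True)) ** 2).sum(1)
            + ((m2 - m2.mean(1, keepdims=True)) ** 2).sum(1)
        ) / (n1 + n2 - 2)
        params = diffexpr.estimate_moderation(s2, n1 + n2 - 2)
        assert params.prior_df == pytest.approx(2.58908803384018, abs=1e-6)
        assert params.prior_var == pytest.approx(0.162656054308373, abs=1e-9)
        for gene, t_ref in [
            ("g0", 0.495330978269218),
            ("g2", -0.0970132722985527),
            ("g150", -0.367461947738142),
            ("g299", -2.18476137590518),
        ]:
            assert rec.loc[gene, "t_statistic"] == pytest.approx(t_ref, abs=1e-9)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.005, 0.03, 0.04), (0.015, 0.04, 0.04)),
            ((0.2,), (0.2,)),
        ],
    )
    def test_step_up_hand_values(self, p, expected):
        assert np.allclose(diffexpr.bh_adjust(np.array(p)), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            diffexpr.bh_adjust(np.array([-0.1]))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.randoms())
    def test_permutation_equivariance(self, p, rnd):
        p = np.asarray(p)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        adjusted = diffexpr.bh_adjust(p)
        assert np.allclose(diffexpr.bh_adjust(p[perm]), adjusted[perm])


class TestCallDegs:
    def _records(self, log2_fc, adj_p):
        return pd.DataFrame(
            {
                "log2_fc": log2_fc,
                "p_value": adj_p,
                "adjusted_p": adj_p,
            },
            index=[f"g{i}" for i in range(len(log2_fc))],
        )

    def test_up_call(self):
        degs = diffexpr.call_degs(self._records([0.7], [0.04]))
        assert degs.up == ["g0"] and degs.down == []

    def test_down_reciprocal_vs_half_rule(self):
        # FC = 2^-0.8 = 0.574: below 1/1.5 but not below 0.5
        rec = self._records([-0.8], [0.04])
        assert diffexpr.call_degs(rec, down_rule="reciprocal").down == ["g0"]
        assert diffexpr.call_degs(rec, down_rule="half").down == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        rec = self._records(rng.normal(0, 1, 50), rng.uniform(0, 1, 50))
        loose = diffexpr.call_degs(rec, adj_p_max=0.2)
        strict = diffexpr.call_degs(rec, adj_p_max=0.05)
        assert strict.genes <= loose.genes


class TestIntersect:
    def test_any_direction(self):
        a = diffexpr.DEGSet("a", up=["x", "y"], down=["z"])
        b = diffexpr.DEGSet("b", up=["y"], down=["z", "w"])
        assert diffexpr.intersect_degs(a, b) == ["y", "z"]
        assert diffexpr.intersect_degs(a, b, mode="same_direction") == ["y", "z"]

    def test_direction_disagreement(self):
        a = diffexpr.DEGSet("a", up=["x"], down=[])
        b = diffexpr.DEGSet("b", up=[], down=["x"])
        assert diffexpr.intersect_degs(a, b, mode="same_direction") == []
        assert diffexpr.intersect_degs(a, b, mode="any_direction") == ["x"]

    def test_up_down_disjoint_enforced(self):
        with pytest.raises(ValidationError):
            diffexpr.DEGSet("a", up=["x"], down=["x"])
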