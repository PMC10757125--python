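"""Synthetic data generator: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest

from diffconet import diffexpr, synthetic_data as sd
from diffconet.io import NONRESPONSE, RESPONSE


class TestConfigValidation:
    def test_infeasible_on_correlation_rejected(self):
        # compound symmetry with m=5 needs rho >= -0.25
        with pytest.raises(sd.ConfigurationError, match="infeasible"):
            sd.BlockSpec(size=5, rho_on=-0.5, rho_off=0.0)

    def test_off_correlation_clamped_to_feasible_range(self):
        block = sd.BlockSpec(size=5, rho_on=0.85, rho_off=-0.3)
        assert block.rho_off_effective == pytest.approx(-0.95 / 4)
        pair = sd.BlockSpec(size=2, rho_on=0.85, rho_off=-0.3)
        assert pair.rho_off_effective == -0.3

    def test_unclassifiable_block_rejected_by_default(self):
        cfg = sd.SimulationConfig(
            n_genes=10, blocks=[sd.BlockSpec(3, 0.85, 0.85)], deg_spec=sd.DEGSpec()
        )
        with pytest.raises(sd.ConfigurationError, match="classified"):
            sd.generate_expression(cfg)

    def test_more_planted_than_genes_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.SimulationConfig(n_genes=5, deg_spec=sd.DEGSpec(n_up=10))


class TestGenerateExpression:
    def test_fixed_seed_bit_reproducible(self):
        cfg = sd.SimulationConfig(n_genes=40, seed=9,
                                  blocks=[sd.BlockSpec(3, 0.8, -0.3)])
        a, _, _ = sd.generate_expression(cfg)
        b, _, _ = sd.generate_expression(cfg)
        assert a.values.equals(b.values)

    def test_perfect_correlation_block(self):
        cfg = sd.SimulationConfig(
            n_genes=6, samples_per_condition=(10, 10),
            blocks=[sd.BlockSpec(3, 1.0, 0.0)], deg_spec=sd.DEGSpec(), seed=0,
        )
        ds, ph, truth = sd.generate_expression(cfg)
        members = sorted({g for a, b, _ in truth.pairs for g in (a, b)})
        sub = ds.values.loc[members, ph.samples(RESPONSE)].to_numpy()
        r = np.corrcoef(sub)
        assert np.allclose(r, 1.0)

    def test_block_correlation_concentrates_at_large_n(self):
        cfg = sd.SimulationConfig(
            n_genes=10, samples_per_condition=(1000, 1000),
            blocks=[sd.BlockSpec(5, 0.85, -0.3)], deg_spec=sd.DEGSpec(), seed=1,
        )
        ds, ph, truth = sd.generate_expression(cfg)
        members = sorted({g for a, b, _ in truth.pairs for g in (a, b)})
        r = np.corrcoef(ds.values.loc[members, ph.samples(RESPONSE)].to_numpy())
        assert abs(r[np.triu_indices(5, 1)].mean() - 0.85) < 0.02

    def test_moderate_n_block_correlation_within_band(self):
        cfg = sd.SimulationConfig(
            n_genes=10, samples_per_condition=(100, 100),
            blocks=[sd.BlockSpec(5, 0.85, -0.3)], deg_spec=sd.DEGSpec(), seed=1,
        )
        ds, ph, truth = sd.generate_expression(cfg)
        members = sorted({g for a, b, _ in truth.pairs for g in (a, b)})
        r = np.corrcoef(ds.values.loc[members, ph.samples(RESPONSE)].to_numpy())
        assert 0.80 <= r[np.triu_indices(5, 1)].mean() <= 0.90

    def test_null_data_yields_no_degs_in_most_seeds(self):
        # delta = 0 everywhere: the downstream moderated t at BH 0.05
        # should call zero genes in at least 95% of seeds
        clean = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = sd.SimulationConfig(
                n_genes=300, samples_per_condition=(20, 20),
                deg_spec=sd.DEGSpec(n_up=0, n_down=0, delta=0.0), seed=seed,
            )
            ds, ph, _ = sd.generate_expression(cfg)
            _, degs = diffexpr.differential_expression(ds, ph)
            clean += not degs.genes
        assert clean >= 0.95 * n_seeds

    def test_truth_classes_match_classifier_rule(self):
        cfg = sd.SimulationConfig(
            n_genes=20,
            blocks=[
                sd.BlockSpec(3, 0.85, -0.3, RESPONSE),
                sd.BlockSpec(3, 0.85, -0.3, NONRESPONSE),
                sd.BlockSpec(2, -0.85, 0.3, RESPONSE),
                sd.BlockSpec(2, -0.85, 0.3, NONRESPONSE),
            ],
            deg_spec=sd.DEGSpec(),
        )
        _, _, truth = sd.generate_expression(cfg)
        classes = {c for _, _, c in truth.pairs}
        assert classes == {"PO", "OP", "NO", "ON"}


class TestGenerateSurvival:
    def _expr(self, n=100, seed=0):
        cfg = sd.SimulationConfig(n_genes=3, samples_per_condition=(n, 0),
                                  deg_spec=sd.DEGSpec(), seed=seed)
        return sd.generate_expression(cfg)[0]

    def test_no_censoring_all_events(self):
        expr = self._expr()
        surv = sd.generate_survival(expr, {}, censor_rate=0.0, seed=1)
        assert surv.event.mean() == 1.0

    def test_censor_calibration(self):
        expr = self._expr(n=1000)
        rate = sd.calibrate_censor_rate(expr, {}, baseline_rate=0.1,
                                        target_fraction=0.3)
        surv = sd.generate_survival(expr, {}, baseline_rate=0.1,
                                    censor_rate=rate, seed=2)
        assert 0.25 <= 1.0 - surv.event.mean() <= 0.35

    def test_deterministic(self):
        expr = self._expr()
        gene = expr.gene_ids[0]
        a = sd.generate_survival(expr, {gene: 0.5}, seed=3)
        b = sd.generate_survival(expr, {gene: 0.5}, seed=3)
        assert a.data.equals(b.data)


class TestGenerateTFTable:
    def test_master_covers_module_and_decoys_avoid_it(self):
        truth = sd.SimulationTruth(hubs={"PONO": ["g1", "g2", "g3", "g4", "g5"]})
        table = sd.generate_tf_table(
            truth, all_genes=[f"g{i}" for i in range(1, 30)],
            n_decoy_tfs=3, targets_per_tf=4, seed=0,
        )
        assert table.targets_of("MASTER_PONO") == {"g1", "g2", "g3", "g4", "g5"}
        for d in (1, 2, 3):
            assert not table.targets_of(f"DECOY{d}") & set(truth.hubs["PONO"])

    def test_zero_decoys_only_master_edges(self):
        truth = sd.SimulationTruth(hubs={"PONO": ["g1", "g2"]})
        table = sd.generate_tf_table(truth, all_genes=["g1", "g2", "g3"],
                                     n_decoy_tfs=0, seed=0)
        assert set(table.edges["tf"]) == {"MASTER_PONO"}


class TestCohortFixture:
    def test_cohort_shapes_and_condition_splits(self):
        bundle = sd.cohort_fixture(seed=7)
        assert bundle.expr_a.n_samples == 53
        assert bundle.expr_b.n_samples == 26
        assert len(bundle.pheno_a.samples(RESPONSE)) == 9
        assert len(bundle.pheno_a.samples(NONRESPONSE)) == 44
        assert len(bundle.pheno_b.samples(RESPONSE)) == 13
        assert len(bundle.pheno_b.samples(NONRESPONSE)) == 13
        assert bundle.expr_a.n_genes == 2000
        assert len(bundle.truth.deg_genes) >= 82

    def test_different_seeds_same_shapes_different_values(self):
        a = sd.cohort_fixture(seed=1)
        b = sd.cohort_fixture(seed=2)
        assert a.expr_a.values.shape == b.expr_a.values.shape
        assert not a.expr_a.values.equals(b.expr_a.values)

    def test_modules_planted_for_both_networks(self):
        bundle = sd.cohort_fixture(seed=3)
        assert len(bundle.truth.hubs["PONO"]) == 5
        assert len(bundle.truth.hubs["OPON"]) == 5
        assert set(bundle.truth.betas) == (
            set(bundle.truth.hubs["PONO"]) | set(bundle.truth.hubs["OPON"])
        )
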