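"""Synthetic-data generators: determinism, planted structure, edge cases."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from tfnet.errors import ConfigError
from tfnet.synthetic import (SyntheticConfig, generate_all,
                             generate_catalogue,
                             generate_cell_line_data, generate_patient_cohort,
                             generate_ppi, generate_survival_cohort,
                             phenotype_counts)

from conftest import small_config


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("replicates_per_line", 4),
        ("prop_cancer", 0.5),              # proportions no longer sum to 1
        ("censoring_rate", 1.0),
        ("n_driver_tfs", 0),
        ("n_cell_lines", 0),
        ("activation_quantile", 1.0),
    ])
    def test_invalid_field_rejected(self, field, value):
        cfg = dataclasses.replace(SyntheticConfig(), **{field: value})
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_module_not_denser_than_background_rejected(self):
        cfg = dataclasses.replace(SyntheticConfig(), ppi_module_prob=0.005)
        with pytest.raises(ConfigError, match="denser"):
            cfg.validate()


class TestGenerateCatalogue:
    def test_saturation_single_tf_targets_every_gene(self):
        cfg = small_config(n_tfs=1, n_driver_tfs=1, n_active_null_tfs=0,
                           n_module_drivers=1, n_genes=30,
                           mean_targets_per_tf=30, module_program_size=0)
        cat = generate_catalogue(cfg)
        assert len(cat.targets_of("TF001")) == 30

    def test_deterministic_under_seed(self):
        cfg = small_config(seed=11)
        a, b = generate_catalogue(cfg), generate_catalogue(cfg)
        pd.testing.assert_frame_equal(a.entries, b.entries)

    def test_total_entry_count_near_expectation(self):
        cfg = SyntheticConfig(n_tfs=345, n_genes=2650, mean_targets_per_tf=20,
                              n_driver_tfs=40, n_active_null_tfs=15)
        cat = generate_catalogue(cfg)
        expected = 345 * 20
        # Poisson sum: SD = sqrt(6900) ~ 83; allow 4 SDs
        assert abs(len(cat) - expected) < 4 * math.sqrt(expected)

    def test_every_tf_has_a_target(self):
        cat = generate_catalogue(small_config())
        assert all(len(cat.targets_of(tf)) >= 1 for tf in cat.tfs)

    def test_module_drivers_share_program_targets(self, small_bundle):
        truth, cat = small_bundle.truth, small_bundle.catalogue
        cover = {}
        for tf in truth.module_drivers:
            for g in cat.targets_of(tf):
                cover[g] = cover.get(g, 0) + 1
        assert max(cover.values()) >= 2


class TestGenerateCellLineData:
    def test_zero_noise_activity_equals_expr_plus_cnv(self):
        """With activity noise 0 and b1 = b2 = 1, a driver's latent
        activity is exactly its expression plus its CNV region value."""
        cfg = small_config(activity_noise_sd=0.0, replicate_noise_sd=0.0,
                           b1=1.0, b2=1.0)
        cat = generate_catalogue(cfg)
        expr, (regions, values), _, truth = generate_cell_line_data(cat, cfg)
        lines = list(truth.activity.columns)
        med = values.set_index("region_id")
        collapsed = expr.collapse_replicates()
        tfs_sorted = sorted(cat.tfs)
        for tf in sorted(truth.driver_tfs)[:5]:
            region = f"R{tfs_sorted.index(tf) + 1:03d}"
            reconstructed = (collapsed.loc[tf, lines].to_numpy()
                             + med.loc[region, lines].to_numpy())
            np.testing.assert_allclose(truth.activity.loc[tf].to_numpy(),
                                       reconstructed, atol=1e-9)

    def test_active_driver_shifts_all_its_targets(self):
        cfg = small_config(replicate_noise_sd=0.0, line_noise_sd=0.0)
        cat = generate_catalogue(cfg)
        expr, _, _, truth = generate_cell_line_data(cat, cfg)
        tf = sorted(truth.driver_tfs)[0]
        active_lines = truth.active.columns[truth.active.loc[tf]]
        assert len(active_lines) > 0
        line = active_lines[0]
        cols = expr.line_columns(line)
        for g in sorted(cat.targets_of(tf))[:10]:
            base = truth.gene_baseline[g]
            assert (expr.values.loc[g, cols] >= base + cfg.target_shift - 1e-9).all()

    def test_quiet_nulls_never_active(self, small_bundle):
        truth = small_bundle.truth
        quiet = truth.all_tfs - truth.driver_tfs - truth.active_null_tfs
        assert len(quiet) > 0
        assert not truth.active.loc[sorted(quiet)].any(axis=None)

    def test_replicate_columns_map_to_lines(self, small_bundle):
        expr = small_bundle.expression
        cfg = small_bundle.config
        assert len(expr.lines) == cfg.n_cell_lines
        for line in expr.lines[:5]:
            assert len(expr.line_columns(line)) == cfg.replicates_per_line

    def test_ground_truth_invariants(self, small_bundle):
        truth, cat = small_bundle.truth, small_bundle.catalogue
        assert truth.driver_tfs <= cat.tfs
        driver_targets = cat.targets_of_many(truth.driver_tfs)
        assert truth.cancer_specific_genes <= driver_targets
        assert truth.decoy_genes.isdisjoint(truth.cancer_specific_genes)
        assert set(truth.survival_genes) <= truth.cancer_specific_genes
        assert truth.driver_tfs and truth.module_nodes and truth.cancer_specific_genes

    def test_bit_identical_under_fixed_seed(self):
        cfg = small_config(seed=17)
        cat = generate_catalogue(cfg)
        a = generate_cell_line_data(cat, cfg)
        b = generate_cell_line_data(cat, cfg)
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[1][0], b[1][0])
        pd.testing.assert_frame_equal(a[1][1], b[1][1])
        assert a[3].cancer_specific_genes == b[3].cancer_specific_genes


class TestGeneratePpi:
    def test_module_clique_at_probability_one(self):
        cfg = small_config(ppi_module_prob=1.0)
        cat = generate_catalogue(cfg)
        _, _, _, truth = generate_cell_line_data(cat, cfg)
        edges = generate_ppi(truth, cfg)
        have = {frozenset((a, b)) for a, b in zip(edges["a"], edges["b"])}
        module = sorted(truth.module_nodes)
        for i, a in enumerate(module):
            for b in module[i + 1:]:
                assert frozenset((a, b)) in have

    def test_background_probability_zero_leaves_only_planted_edges(self):
        cfg = small_config(ppi_background_prob=0.0, ppi_peripheral_prob=0.0)
        cat = generate_catalogue(cfg)
        _, _, _, truth = generate_cell_line_data(cat, cfg)
        edges = generate_ppi(truth, cfg)
        wired = truth.module_nodes | (truth.driver_tfs - truth.unmapped_tfs)
        for a, b in zip(edges["a"], edges["b"]):
            assert {a, b} <= wired

    def test_all_evidence_counts_at_least_two(self, small_bundle):
        assert (small_bundle.ppi_edges["evidence"] >= 2).all()

    def test_unmapped_tfs_absent_from_graph(self, small_bundle):
        truth, edges = small_bundle.truth, small_bundle.ppi_edges
        nodes = set(edges["a"]) | set(edges["b"])
        assert truth.unmapped_tfs
        assert nodes.isdisjoint(truth.unmapped_tfs)

    def test_module_not_denser_than_background_rejected(self):
        cfg = small_config(ppi_module_prob=1.0)
        cat = generate_catalogue(cfg)
        _, _, _, truth = generate_cell_line_data(cat, cfg)
        bad = dataclasses.replace(cfg, ppi_module_prob=0.005)
        with pytest.raises(ConfigError):
            generate_ppi(truth, bad)


class TestGeneratePatientCohort:
    def test_proportion_rounding_500_patients(self):
        counts = phenotype_counts(500, SyntheticConfig())
        assert (counts["cancer"], counts["inflammation"], counts["healthy"]) \
            == (390, 40, 70)

    def test_decoy_shifted_in_cancer_and_inflammation(self, small_bundle):
        truth = small_bundle.truth
        expr, phen = small_bundle.patient_expr, small_bundle.phenotypes
        g = sorted(truth.decoy_genes)[0]
        vals = expr.values.loc[g]
        m_c = vals[phen[phen == "cancer"].index].mean()
        m_i = vals[phen[phen == "inflammation"].index].mean()
        m_h = vals[phen[phen == "healthy"].index].mean()
        # planted shift is 1.5 noise SDs; group means carry ~0.3 SE noise
        assert m_c - m_h > 0.75 and m_i - m_h > 0.75

    def test_cancer_specific_shifted_in_cancer_only(self, small_bundle):
        truth = small_bundle.truth
        expr, phen = small_bundle.patient_expr, small_bundle.phenotypes
        g = sorted(truth.cancer_specific_genes)[0]
        vals = expr.values.loc[g]
        m_c = vals[phen[phen == "cancer"].index].mean()
        m_i = vals[phen[phen == "inflammation"].index].mean()
        m_h = vals[phen[phen == "healthy"].index].mean()
        assert m_c - m_h > 0.75
        assert abs(m_i - m_h) < 0.75  # null contrast, ~0.38 SE

    def test_zero_effect_warns(self, caplog):
        cfg = small_config(cancer_effect=0.0)
        cat = generate_catalogue(cfg)
        _, _, _, truth = generate_cell_line_data(cat, cfg)
        with caplog.at_level("WARNING"):
            generate_patient_cohort(["G0001"], truth, cfg)
        assert any("cancer_effect" in r.message for r in caplog.records)


class TestGenerateSurvivalCohort:
    def test_zero_censoring_observes_every_event(self):
        cfg = small_config(censoring_rate=0.0)
        cat = generate_catalogue(cfg)
        _, _, _, truth = generate_cell_line_data(cat, cfg)
        _, clin = generate_survival_cohort(["G0001", "G0002"], truth, cfg, "C1")
        assert (clin["event"] == 1).all()
        assert (clin["time"] > 0).all()

    def test_censoring_rate_roughly_respected(self):
        cfg = small_config(censoring_rate=0.4, cohort_size=400)
        cat = generate_catalogue(cfg)
        _, _, _, truth = generate_cell_line_data(cat, cfg)
        _, clin = generate_survival_cohort(["G0001"], truth, cfg, "C1")
        frac_censored = 1 - clin["event"].mean()
        assert 0.25 < frac_censored < 0.55

    def test_invalid_censoring_rate_rejected(self):
        with pytest.raises(ConfigError):
            small_config(censoring_rate=-0.1).validate()


class TestGenerateAll:
    def test_bundle_is_deterministic(self):
        cfg = small_config(seed=23)
        a, b = generate_all(cfg), generate_all(cfg)
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        pd.testing.assert_frame_equal(a.ppi_edges, b.ppi_edges)
        pd.testing.assert_frame_equal(a.patient_expr.values, b.patient_expr.values)
        for (la, ea, ca), (lb, eb, cb) in zip(a.survival_cohorts, b.survival_cohorts):
            assert la == lb
            pd.testing.assert_frame_equal(ca, cb)
        assert a.annotation_sets == b.annotation_sets

    def test_annotation_sets_cover_planted_genes(self, small_bundle):
        union = (small_bundle.annotation_sets["secreted"]
                 | small_bundle.annotation_sets["transmembrane"])
        assert small_bundle.truth.cancer_specific_genes <= union
        assert small_bundle.truth.decoy_genes <= union
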