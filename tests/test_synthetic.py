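"""Synthetic generator: determinism, structure, planted signal, couplings."""

import numpy as np
import pandas as pd
import pytest

from tics import (
    GeneratorConfig,
    generate_chemo_labels,
    generate_cohorts,
    generate_mutations,
)
from tics.aux import compute_tmb, spearman_assoc
from tics.synthetic import CELL_NAMES, cell_gene_sets, signature_collection


def _small(**kw):
    defaults = dict(n_cohorts=2, samples_per_cohort=40, n_genes=120, genes_per_cell=4, seed=3)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("genes_per_cell", 2, "genes_per_cell"),
            ("n_genes", 50, "n_genes"),
            ("abundance_dispersion", -1.0, "abundance_dispersion"),
            ("censoring_rate", 0.0, "censoring_rate"),
            ("planted_effects", {"No Such Cell": 1.0}, "cell names"),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value, match):
        kwargs = dict(n_cohorts=2, samples_per_cohort=10, n_genes=120, genes_per_cell=4)
        kwargs[field] = value
        with pytest.raises(ValueError, match=match):
            GeneratorConfig(**kwargs)

    def test_default_is_recovery_scenario(self):
        cfg = GeneratorConfig()
        assert cfg.n_cohorts == 4 and cfg.samples_per_cohort == 150
        gammas = sorted(cfg.planted_effects.values())
        assert gammas == [-0.6, -0.6, -0.6, -0.6, 0.6, 0.6]


class TestStructure:
    def test_disjoint_gene_blocks(self):
        cfg = _small()
        _, assignment = cell_gene_sets(cfg)
        seen = set()
        for genes in assignment.values():
            assert not (seen & set(genes))
            seen |= set(genes)

    def test_overlap_fraction_shares_genes(self):
        cfg = _small(overlap_fraction=0.5)
        _, assignment = cell_gene_sets(cfg)
        cells = list(assignment)
        shared = set(assignment[cells[0]]) & set(assignment[cells[1]])
        assert len(shared) == 2  # ceil(0.5 * 4)

    def test_deterministic_under_seed(self):
        cfg = _small()
        b1, t1 = generate_cohorts(cfg)
        b2, t2 = generate_cohorts(_small())
        for x, y in zip(b1, b2):
            pd.testing.assert_frame_equal(x.expression.values, y.expression.values)
            pd.testing.assert_frame_equal(x.survival.data, y.survival.data)
        pd.testing.assert_series_equal(t1.true_linear_predictor, t2.true_linear_predictor)

    def test_adding_cohort_preserves_earlier_ones(self):
        b2, _ = generate_cohorts(_small(n_cohorts=2))
        b3, _ = generate_cohorts(_small(n_cohorts=3))
        for x, y in zip(b2, b3):
            pd.testing.assert_frame_equal(x.expression.values, y.expression.values)
            pd.testing.assert_frame_equal(x.survival.data, y.survival.data)

    def test_abundance_positive_finite(self):
        _, truth = generate_cohorts(_small())
        a = truth.latent_abundance.to_numpy()
        assert np.isfinite(a).all() and (a > 0).all()

    def test_signature_collection_matches_assignment(self):
        cfg = _small()
        gmt = signature_collection(cfg)
        assert gmt.set_names == list(CELL_NAMES[: cfg.n_cells])


class TestSurvivalGeneration:
    def test_heavy_censoring_limit(self):
        cfg = _small(censoring_rate=1000.0)
        bundles, _ = generate_cohorts(cfg)
        events = np.concatenate([b.survival.data["event"] for b in bundles])
        assert events.mean() < 0.01

    def test_marker_genes_track_abundance(self):
        cfg = _small(expression_noise_sd=0.3)
        bundles, truth = generate_cohorts(cfg)
        cell = CELL_NAMES[0]
        genes = truth.cell_gene_assignment[cell]
        b = bundles[0]
        abund = truth.latent_abundance.loc[cell, b.expression.sample_ids]
        mean_expr = b.expression.values.loc[genes].mean(axis=0)
        rho, p = spearman_assoc(np.log(abund.to_numpy()), mean_expr.to_numpy())
        assert rho > 0.5 and p < 1e-4

    def test_null_model_no_systematic_effect(self):
        """With all gamma = 0, per-cell median-split Cox p is uniform."""
        from tics.meta import per_cohort_cell_cox, pool_cox_table
        from tics.ssgsea import ssgsea_matrix

        ps = []
        for seed in range(8):
            cfg = _small(planted_effects={}, seed=seed)
            bundles, _ = generate_cohorts(cfg)
            gmt = signature_collection(cfg)
            enrich = [ssgsea_matrix(b.expression, gmt, min_set_size=3) for b in bundles]
            pooled = pool_cox_table(per_cohort_cell_cox(bundles, enrich))
            ps.extend(e.p for e in pooled)
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() == pytest.approx(0.05, abs=0.04)
        assert ps.mean() == pytest.approx(0.5, abs=0.1)


class TestMutations:
    def test_mean_tmb_by_construction(self):
        """mu0 = log(38 * 2), coding_mb = 38 -> mean TMB about 2/Mb."""
        cfg = _small(tmb_coupling=0.0, samples_per_cohort=150)
        _, truth = generate_cohorts(cfg)
        muts = generate_mutations(truth, cfg)
        tmb = compute_tmb(muts, coding_mb=cfg.coding_mb,
                          sample_universe=truth.cohort_of.index).tmb
        assert tmb.mean() == pytest.approx(2.0, rel=0.1)

    def test_zero_coupling_no_association(self):
        rhos = []
        for seed in range(6):
            cfg = _small(tmb_coupling=0.0, seed=seed, samples_per_cohort=100)
            _, truth = generate_cohorts(cfg)
            muts = generate_mutations(truth, cfg)
            tmb = compute_tmb(muts, sample_universe=truth.cohort_of.index).tmb
            rho, _ = spearman_assoc(truth.protective_lp.to_numpy(), tmb.to_numpy())
            rhos.append(rho)
        assert np.mean(rhos) == pytest.approx(0.0, abs=0.05)

    def test_negative_coupling_negative_sign(self):
        signs = []
        for seed in range(10):
            cfg = _small(tmb_coupling=-0.5, seed=seed, samples_per_cohort=150)
            _, truth = generate_cohorts(cfg)
            muts = generate_mutations(truth, cfg)
            tmb = compute_tmb(muts, sample_universe=truth.cohort_of.index).tmb
            rho, _ = spearman_assoc(truth.protective_lp.to_numpy(), tmb.to_numpy())
            signs.append(rho < 0)
        assert np.mean(signs) >= 0.9

    def test_driver_gene_present(self):
        cfg = _small()
        _, truth = generate_cohorts(cfg)
        muts = generate_mutations(truth, cfg)
        counts = muts.data[muts.data["coding"]]["gene"].value_counts()
        assert counts.idxmax() == "KRAS"


class TestChemoLabels:
    def test_deterministic(self):
        cfg = _small()
        _, truth = generate_cohorts(cfg)
        c1 = generate_chemo_labels(truth, cfg)
        c2 = generate_chemo_labels(truth, cfg)
        pd.testing.assert_frame_equal(c1.data, c2.data)

    def test_zero_slope_uninformative(self):
        from tics import roc_auc

        aucs = []
        for seed in range(10):
            cfg = _small(chemo_slope=0.0, seed=seed, samples_per_cohort=120,
                         chemo_fraction=1.0)
            _, truth = generate_cohorts(cfg)
            chemo = generate_chemo_labels(truth, cfg)
            labels = (chemo.data.set_index("sample_id")["response"] == "CR").astype(int)
            scores = truth.protective_lp.reindex(labels.index)
            aucs.append(roc_auc(scores.to_numpy(), labels.to_numpy()).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_auc_monotone_in_slope(self):
        from tics import roc_auc

        mean_aucs = []
        for slope in [0.0, 0.5, 1.0, 2.0, 4.0]:
            aucs = []
            for seed in range(5):
                cfg = _small(chemo_slope=slope, seed=seed, samples_per_cohort=150,
                             chemo_fraction=1.0)
                _, truth = generate_cohorts(cfg)
                chemo = generate_chemo_labels(truth, cfg)
                labels = (chemo.data.set_index("sample_id")["response"] == "CR").astype(int)
                scores = truth.protective_lp.reindex(labels.index)
                aucs.append(roc_auc(scores.to_numpy(), labels.to_numpy()).auc)
            mean_aucs.append(np.mean(aucs))
        assert all(b > a - 0.02 for a, b in zip(mean_aucs, mean_aucs[1:]))
        assert mean_aucs[-1] > 0.85

    def test_impossible_intercept_yields_no_cr(self):
        from tics import roc_auc

        cfg = _small(chemo_intercept=-50.0, chemo_fraction=1.0)
        _, truth = generate_cohorts(cfg)
        chemo = generate_chemo_labels(truth, cfg)
        labels = (chemo.data["response"] == "CR").astype(int)
        assert labels.sum() == 0
        with pytest.raises(ValueError):
            roc_auc(np.arange(len(labels), dtype=float), labels.to_numpy())

    def test_no_chemo_patients_unlabeled(self):
        cfg = _small(chemo_fraction=0.5)
        _, truth = generate_cohorts(cfg)
        chemo = generate_chemo_labels(truth, cfg).data.set_index("sample_id")
        no_chemo = chemo[chemo["received_chemo"] == 0]
        assert (no_chemo["response"] == "unknown").all()
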