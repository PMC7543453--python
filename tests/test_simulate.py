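import numpy as np
import pandas as pd
import pytest

import mndprofiler as mp
from mndprofiler.classification import NOT_DETECTABLE
from mndprofiler.io import ValidationError
from mndprofiler.simulate import CANONICAL_BREAKDOWN, generative_tpm_means


def _recovered_counts(cfg):
    cm, sheet, truth = mp.simulate_counts(cfg)
    means = mp.donor_mean(mp.apply_detection_floor(mp.rpkm(cm)), sheet)
    panel = truth.to_panel()
    return mp.summarize(mp.classify_panel(means, panel), panel), truth


def _accuracy(cfg):
    cm, sheet, truth = mp.simulate_counts(cfg)
    means = mp.donor_mean(mp.apply_detection_floor(mp.rpkm(cm)), sheet)
    cls = mp.classify_panel(means, truth.to_panel())
    hits = sum(c.category == truth.planted_category[c.gene_symbol] for c in cls)
    return hits / len(cls)


class TestSimulateCounts:
    def test_same_seed_is_bit_identical(self):
        cfg = mp.SimulationConfig(n_genes=40, seed=11)
        cm1, sheet1, truth1 = mp.simulate_counts(cfg)
        cm2, sheet2, truth2 = mp.simulate_counts(cfg)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_series_equal(cm1.gene_lengths, cm2.gene_lengths)
        pd.testing.assert_series_equal(
            truth1.planted_category, truth2.planted_category
        )

    def test_poisson_limit_recovers_all_labels(self):
        cfg = mp.SimulationConfig(n_genes=60, nb_dispersion=0.0, fold_change=10.0,
                                  seed=4)
        assert _accuracy(cfg) == 1.0

    def test_not_detectable_genes_have_zero_counts(self):
        cfg = mp.canonical_config(seed=9)
        cm, _, truth = mp.simulate_counts(cfg)
        nd = truth.planted_category[truth.planted_category == NOT_DETECTABLE].index
        assert (cm.counts.loc[nd] == 0).all().all()

    def test_canonical_distribution_recovered(self):
        summary, truth = _recovered_counts(mp.canonical_config(seed=3))
        expected = truth.planted_category.value_counts()
        for cat, n in expected.items():
            assert summary.counts[cat] == n

    def test_canonical_breakdown_sums_to_abstract_counts(self):
        totals = {}
        for grp in CANONICAL_BREAKDOWN.values():
            for cat, n in grp.items():
                totals[cat] = totals.get(cat, 0) + n
        assert totals == {"CN": 50, "F": 41, "LB": 26, "iPSC": 22, "PBMC": 14,
                          NOT_DETECTABLE: 15}

    def test_expected_library_size_respected(self):
        cfg = mp.SimulationConfig(n_genes=100, library_size=500_000, seed=5)
        cm, _, _ = mp.simulate_counts(cfg)
        totals = cm.counts.sum(axis=0)
        # per-sample totals within sampling error; their mean much tighter
        assert np.allclose(totals, 500_000, rtol=0.25)
        assert abs(totals.mean() - 500_000) / 500_000 < 0.05

    def test_accuracy_non_decreasing_in_fold_change(self):
        accs = []
        for fold in (1.3, 3.0, 10.0):
            vals = [
                _accuracy(
                    mp.SimulationConfig(n_genes=60, fold_change=fold,
                                        nb_dispersion=0.5, seed=s)
                )
                for s in range(3)
            ]
            accs.append(np.mean(vals))
        assert accs[0] <= accs[1] + 0.05
        assert accs[1] <= accs[2] + 0.05
        assert accs[2] > accs[0]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            mp.SimulationConfig(n_genes=0)
        with pytest.raises(ValidationError):
            mp.SimulationConfig(fold_change=1.0)
        with pytest.raises(ValidationError):
            mp.SimulationConfig(n_genes=5, planted_categories=("CN",) * 4)
        with pytest.raises(ValidationError):
            mp.SimulationConfig(n_genes=2, planted_categories=("CN", "XX"))


class TestSimulateReference:
    def test_perfect_correlation_ranks_own_column_first(self):
        cfg = mp.SimulationConfig(n_genes=80, seed=21)
        cm, sheet, truth = mp.simulate_counts(cfg)
        ref = mp.simulate_reference(cfg, truth, rho=1.0)
        sim = mp.spearman_similarity(mp.tpm(cm), ref)
        groups = sheet.group_of()
        for sample in sim.rho.index:
            assert sim.rho.loc[sample].idxmax() == groups[sample]

    def test_zero_correlation_is_not_systematically_maximal(self):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = mp.SimulationConfig(n_genes=60, seed=seed)
            cm, sheet, truth = mp.simulate_counts(cfg)
            ref = mp.simulate_reference(cfg, truth, rho=0.0)
            sim = mp.group_significance(
                mp.spearman_similarity(mp.tpm(cm), ref), sheet.group_of()
            )
            best = (
                sim.group_tests.sort_values("neg_log10_p", ascending=False)
                .groupby("group")
                .head(1)
            )
            wins += sum(
                row["reference"] == truth.reference_assignment[row["group"]]
                for _, row in best.iterrows()
            )
        # 5 groups x 20 seeds; at rho=0 the planted pairing must not dominate
        assert wins < 0.6 * 5 * n_seeds

    def test_seed_reproducibility(self):
        cfg = mp.SimulationConfig(n_genes=30, seed=2)
        _, _, truth = mp.simulate_counts(cfg)
        r1 = mp.simulate_reference(cfg, truth, rho=0.9)
        r2 = mp.simulate_reference(cfg, truth, rho=0.9)
        pd.testing.assert_frame_equal(r1.values, r2.values)

    def test_invalid_rho_rejected(self):
        cfg = mp.SimulationConfig(n_genes=10, seed=0)
        _, _, truth = mp.simulate_counts(cfg)
        with pytest.raises(ValidationError, match="correlation"):
            mp.simulate_reference(cfg, truth, rho=1.5)

    def test_reference_columns_are_tpm(self):
        cfg = mp.SimulationConfig(n_genes=25, seed=6)
        _, _, truth = mp.simulate_counts(cfg)
        ref = mp.simulate_reference(cfg, truth, rho=0.8)
        assert np.allclose(ref.values.sum(axis=0), 1e6, rtol=1e-9)


class TestSimulateGoCatalog:
    def test_pure_winner_term_has_depressed_coverage_elsewhere(self):
        cfg = mp.canonical_config(seed=12)
        cm, sheet, truth = mp.simulate_counts(cfg)
        catalog = mp.simulate_go_catalog(
            truth, n_terms=1, set_size=15, enriched_cell_type="CN",
            enrichment=np.inf, seed=1,
        )
        means = mp.donor_mean(mp.apply_detection_floor(mp.rpkm(cm)), sheet)
        cov = mp.coverage(means, catalog, reference="CN")
        term = next(iter(catalog)).term_id
        for ct in ("PBMC", "LB", "F", "iPSC"):
            assert cov.normalized.loc[term, ct] <= 1.0

    def test_set_size_exceeding_gene_count_rejected(self):
        cfg = mp.SimulationConfig(n_genes=10, seed=0)
        _, _, truth = mp.simulate_counts(cfg)
        with pytest.raises(ValidationError, match="set_size"):
            mp.simulate_go_catalog(truth, set_size=11)

    def test_memberships_recorded_in_truth(self):
        cfg = mp.SimulationConfig(n_genes=30, seed=0)
        _, _, truth = mp.simulate_counts(cfg)
        catalog = mp.simulate_go_catalog(truth, n_terms=2, set_size=5, seed=3)
        for gs in catalog:
            assert truth.go_memberships[gs.term_id] == gs.genes


class TestSimulateQpcr:
    def test_noise_free_model_inverts_exactly(self):
        cfg = mp.canonical_config(seed=8)
        _, _, truth = mp.simulate_counts(cfg)
        plate = mp.simulate_qpcr(truth, cfg, noise_sd=0.0)
        rel = mp.relative_expression(mp.delta_ct(plate))
        for gene, ref_line in rel.reference_lines.items():
            planted = truth.planted_category[gene]
            assert ref_line == planted
            for line in ("PBMC", "LB", "F", "iPSC", "CN"):
                expected = 1.0 if line == planted else 1.0 / cfg.fold_change
                assert rel.relative_of(gene, line) == pytest.approx(expected)

    def test_triplicates_present_for_every_gene_and_line(self):
        cfg = mp.canonical_config(seed=8)
        _, _, truth = mp.simulate_counts(cfg)
        plate = mp.simulate_qpcr(truth, cfg)
        sizes = plate.records.groupby(["gene", "cell_line"]).size()
        assert (sizes == 3).all()

    def test_planted_nd_gene_yields_no_ct(self):
        cfg = mp.canonical_config(seed=8)
        _, _, truth = mp.simulate_counts(cfg)
        nd_gene = truth.planted_category[
            truth.planted_category == NOT_DETECTABLE
        ].index[0]
        plate = mp.simulate_qpcr(truth, cfg, genes=[nd_gene])
        target = plate.records[plate.records["gene"] == nd_gene]
        assert target["ct"].isna().all()


def test_generative_tpm_means_columns_normalized():
    cfg = mp.SimulationConfig(n_genes=40, seed=1)
    _, _, truth = mp.simulate_counts(cfg)
    tm = generative_tpm_means(cfg, truth)
    assert np.allclose(tm.sum(axis=0), 1e6)
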