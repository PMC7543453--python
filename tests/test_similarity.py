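import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import mndprofiler as mp
from mndprofiler._stats import exact_ranksum_p_greater
from mndprofiler.io import ValidationError
from mndprofiler.normalization import Unit
from mndprofiler.similarity import sample_dissimilarity


def _tpm(df):
    return mp.AbundanceMatrix(df.astype(float), Unit.TPM)


def brute_force_ranksum_p(test, background):
    """Independent oracle: enumerate every rank assignment explicitly."""
    combined = np.concatenate([test, background])
    ranks = rankdata(combined)
    m = len(test)
    observed = ranks[:m].sum()
    count = total = 0
    for idx in itertools.combinations(range(len(combined)), m):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-9:
            count += 1
    return count / total


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        genes = [f"g{i}" for i in range(6)]
        ref = pd.DataFrame({"r": [1, 2, 3, 4, 5, 6]}, index=genes)
        bulk = pd.DataFrame({"b": np.exp(ref["r"])}, index=genes)
        sim = mp.spearman_similarity(_tpm(bulk), _tpm(ref))
        assert sim.rho.loc["b", "r"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        genes = [f"g{i}" for i in range(5)]
        ref = pd.DataFrame({"r": [1, 2, 3, 4, 5]}, index=genes)
        bulk = pd.DataFrame({"b": [5, 4, 3, 2, 1]}, index=genes)
        sim = mp.spearman_similarity(_tpm(bulk), _tpm(ref))
        assert sim.rho.loc["b", "r"] == pytest.approx(-1.0)

    def test_four_point_worked_example(self):
        # ranks (1,2,3,4) vs (1,2,4,3): rho = 1 - 6*2/(4*15) = 0.8
        genes = ["a", "b", "c", "d"]
        bulk = pd.DataFrame({"b": [1, 2, 3, 4]}, index=genes)
        ref = pd.DataFrame({"r": [1, 2, 4, 3]}, index=genes)
        sim = mp.spearman_similarity(_tpm(bulk), _tpm(ref))
        assert sim.rho.loc["b", "r"] == pytest.approx(0.8)

    def test_too_few_shared_genes_rejected(self):
        bulk = pd.DataFrame({"b": [1, 2]}, index=["a", "b"])
        ref = pd.DataFrame({"r": [1, 2]}, index=["b", "c"])
        with pytest.raises(ValidationError, match="1 gene"):
            mp.spearman_similarity(_tpm(bulk), _tpm(ref))


class TestExactRankSum:
    def test_worked_example_matches_enumeration(self):
        test = np.array([0.9, 0.8])
        bg = np.array([0.9, 0.8, 0.2, 0.15, 0.1, 0.05])
        assert exact_ranksum_p_greater(test, bg) == pytest.approx(
            brute_force_ranksum_p(test, bg)
        )

    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5, 6, 7, 8])
    def test_matches_enumeration_for_all_small_sizes(self, m):
        rng = np.random.default_rng(m)
        test = rng.normal(0.5, 0.3, size=m)
        bg = np.round(rng.normal(0.0, 0.5, size=8), 1)  # rounding forces ties
        bg[:2] = test[:2] if m >= 2 else bg[:2]  # overlap with the test set
        assert exact_ranksum_p_greater(test, bg) == pytest.approx(
            brute_force_ranksum_p(test, bg)
        )

    def test_strictly_dominant_test_set_attains_minimum(self):
        test = np.array([10.0, 11.0, 12.0])
        bg = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        from math import comb

        assert exact_ranksum_p_greater(test, bg) == pytest.approx(1 / comb(8, 3))

    def test_normal_approximation_close_to_exact(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(7)
        for m in (8, 9, 10):
            test = rng.normal(0.3, 1.0, size=m)
            bg = rng.normal(0.0, 1.0, size=10)
            exact = exact_ranksum_p_greater(test, bg)
            approx = mannwhitneyu(test, bg, alternative="greater",
                                  method="asymptotic").pvalue
            assert abs(exact - approx) < 0.02


class TestGroupSignificance:
    def _sim(self, rho_df):
        return mp.SimilarityResult(rho=rho_df, n_shared_genes=100)

    def test_degenerate_background_gives_p_one(self):
        rho = pd.DataFrame(0.5, index=["s1", "s2"], columns=["r1", "r2"])
        with pytest.warns(UserWarning, match="degenerate"):
            out = mp.group_significance(self._sim(rho), {"s1": "A", "s2": "A"})
        assert (out.group_tests["p"] == 1.0).all()
        assert (out.group_tests["neg_log10_p"] == 0.0).all()

    def test_p_matches_enumeration_oracle(self):
        rho = pd.DataFrame(
            {"r1": [0.9, 0.8], "r2": [0.2, 0.15], "r3": [0.1, 0.05]},
            index=["s1", "s2"],
        )
        out = mp.group_significance(self._sim(rho), {"s1": "A", "s2": "A"})
        row = out.group_tests.query("group == 'A' and reference == 'r1'").iloc[0]
        expected = brute_force_ranksum_p(
            np.array([0.9, 0.8]), rho.values.ravel()
        )
        assert row["p"] == pytest.approx(expected)
        assert row["neg_log10_p"] == pytest.approx(-np.log10(expected))

    def test_background_others_excludes_test_cells(self):
        rho = pd.DataFrame(
            {"r1": [0.9, 0.8], "r2": [0.2, 0.15]}, index=["s1", "s2"]
        )
        out = mp.group_significance(
            self._sim(rho), {"s1": "A", "s2": "A"}, background="others"
        )
        row = out.group_tests.query("group == 'A' and reference == 'r1'").iloc[0]
        expected = brute_force_ranksum_p(
            np.array([0.9, 0.8]), np.array([0.2, 0.15])
        )
        assert row["p"] == pytest.approx(expected)

    def test_missing_group_label_rejected(self):
        rho = pd.DataFrame({"r1": [0.9, 0.8]}, index=["s1", "s2"])
        with pytest.raises(ValidationError, match="s2"):
            mp.group_significance(self._sim(rho), {"s1": "A"})


class TestClassicalMds:
    def test_three_collinear_points(self):
        D = pd.DataFrame(
            [[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        res = mp.classical_mds(D, k=1)
        coords = res.coordinates["dim1"].values
        recovered = np.abs(coords[:, None] - coords[None, :])
        assert np.allclose(recovered, D.values, atol=1e-9)

    def test_identical_samples_collapse_to_origin(self):
        D = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        res = mp.classical_mds(D, k=2)
        assert np.allclose(res.coordinates.values, 0.0)

    def test_recovers_euclidean_embeddable_distances(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(6)]
        res = mp.classical_mds(pd.DataFrame(D, index=labels, columns=labels), k=3)
        C = res.coordinates.values
        rec = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, D, atol=1e-8)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()

    def test_asymmetric_input_rejected(self):
        D = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValidationError, match="symmetric"):
            mp.classical_mds(D, k=1)

    def test_dissimilarity_metric_options(self, canonical_run):
        cfg, cm, *_ = canonical_run
        t = mp.tpm(cm)
        D = sample_dissimilarity(t, metric="1-spearman")
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0.0)
        D2 = sample_dissimilarity(t, metric="euclidean-log1p")
        assert (D2.values >= 0).all()


def test_planted_group_attains_maximal_significance(canonical_run):
    cfg, cm, sheet, truth, *_ = canonical_run
    bulk = mp.tpm(cm)
    ref = mp.simulate_reference(cfg, truth, rho=0.95)
    sim = mp.group_significance(
        mp.spearman_similarity(bulk, ref), sheet.group_of()
    )
    best = (
        sim.group_tests.sort_values("neg_log10_p", ascending=False)
        .groupby("group")
        .head(1)
    )
    for _, row in best.iterrows():
        assert row["reference"] == truth.reference_assignment[row["group"]]
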