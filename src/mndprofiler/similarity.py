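"""Similarity of bulk samples to single-cell reference profiles.

Each bulk sample is compared with each reference cell-type profile by
Spearman rank correlation over the genes shared between the two matrices
(TPM in, but any strictly monotone per-column transform gives identical
results). Per bulk group (typically a cell type), similarity to a reference
column is then tested against the background of all pairwise comparisons
with a one-sided Wilcoxon rank-sum test ("is this group's rho larger than a
comparison drawn at random?"); significance is reported as -log10 p. Small
test sets use an exact enumeration of rank assignments; larger ones fall
back to the tie-corrected normal approximation.

Classical (Torgerson) multidimensional scaling of inter-sample
dissimilarities is provided for the sample-ordination overview plot.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from ._stats import exact_ranksum_p_greater
from .io import ValidationError
from .normalization import AbundanceMatrix, Unit

__all__ = [
    "SimilarityResult",
    "OrdinationResult",
    "spearman_similarity",
    "group_significance",
    "classical_mds",
    "sample_dissimilarity",
    "average_reference_columns",
]

#: p-values are floored here before taking -log10, to avoid infinities.
P_FLOOR = np.finfo(float).tiny


@dataclasses.dataclass
class SimilarityResult:
    """Bulk-sample x reference-cell-type Spearman matrix plus group tests."""

    rho: pd.DataFrame                     # samples x reference columns
    n_shared_genes: int
    group_tests: pd.DataFrame | None = None  # group, reference, p, neg_log10_p, p_bh

    def __post_init__(self) -> None:
        vals = self.rho.values
        if np.nanmax(np.abs(vals)) > 1 + 1e-12:
            raise ValidationError("Spearman coefficients must lie in [-1, 1]")


@dataclasses.dataclass
class OrdinationResult:
    """Sample coordinates from classical MDS plus the eigenvalue spectrum."""

    coordinates: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray    # all n eigenvalues, non-increasing


def spearman_similarity(
    bulk: AbundanceMatrix, reference: AbundanceMatrix
) -> SimilarityResult:
    """Spearman rho of every bulk sample against every reference column.

    Correlations are computed over the intersection of gene ids (midrank
    ties); fewer than 3 shared genes is an error.
    """
    bulk.require_unit(Unit.TPM)
    reference.require_unit(Unit.TPM)
    shared = bulk.values.index.intersection(reference.values.index)
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} gene(s) shared between bulk and reference; need >= 3"
        )
    b = bulk.values.loc[shared]
    r = reference.values.loc[shared]
    nb = b.shape[1]
    corr = _spearman_matrix(np.hstack([b.values, r.values]))
    rho = pd.DataFrame(corr[:nb, nb:], index=b.columns, columns=r.columns)
    return SimilarityResult(rho=rho, n_shared_genes=len(shared))


def _spearman_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs Spearman rho of the columns of X (midrank ties)."""
    ranks = np.apply_along_axis(rankdata, 0, X)
    return np.corrcoef(ranks, rowvar=False)


def group_significance(
    sim: SimilarityResult,
    bulk_groups: Mapping[str, str],
    background: str = "all",
    exact_max: int = 10,
) -> SimilarityResult:
    """Rank-sum test of each (bulk group, reference column) pair.

    The test set is the group's rho values for that reference column; the
    background is every entry of the rho matrix (``background="all"``, the
    default) or every entry outside the test set (``"others"``). The
    alternative is one-sided greater. Exact enumeration is used for test
    sets of at most ``exact_max`` values, a tie-corrected normal
    approximation beyond that. A degenerate background (all values equal)
    yields p = 1 with a warning.
    """
    if background not in ("all", "others"):
        raise ValueError("background must be 'all' or 'others'")
    missing = [s for s in sim.rho.index if s not in bulk_groups]
    if missing:
        raise ValidationError(f"bulk samples without a group label: {missing}")
    all_values = sim.rho.values.ravel()
    groups = sorted(set(bulk_groups[s] for s in sim.rho.index))
    rows = []
    for grp in groups:
        samples = [s for s in sim.rho.index if bulk_groups[s] == grp]
        for ref in sim.rho.columns:
            test = sim.rho.loc[samples, ref].values.astype(float)
            if background == "all":
                bg = all_values
            else:
                mask = np.ones(sim.rho.shape, dtype=bool)
                mask[[sim.rho.index.get_loc(s) for s in samples],
                     sim.rho.columns.get_loc(ref)] = False
                bg = sim.rho.values[mask]
            # total comparisons must exceed the group size
            total = len(bg) if background == "all" else len(bg) + len(test)
            if total < len(test) + 1:
                raise ValidationError(
                    f"background too small for group {grp!r} vs {ref!r}"
                )
            pooled = np.concatenate([test, bg])
            if np.all(pooled == pooled[0]):
                warnings.warn(
                    f"degenerate background for group {grp!r} vs {ref!r}: "
                    "all values identical; p set to 1"
                )
                p = 1.0
            elif len(test) <= exact_max:
                p = exact_ranksum_p_greater(test, bg)
            else:
                p = mannwhitneyu(test, bg, alternative="greater",
                                 method="asymptotic").pvalue
            p = min(max(float(p), P_FLOOR), 1.0)
            rows.append({"group": grp, "reference": ref, "p": p,
                         "neg_log10_p": -np.log10(p)})
    tests = pd.DataFrame(rows)
    tests["p_bh"] = multipletests(tests["p"], method="fdr_bh")[1]
    return SimilarityResult(rho=sim.rho, n_shared_genes=sim.n_shared_genes,
                            group_tests=tests)


def sample_dissimilarity(
    am: AbundanceMatrix, metric: str = "1-spearman"
) -> pd.DataFrame:
    """Symmetric sample x sample dissimilarity matrix for ordination.

    ``"1-spearman"`` (default) uses one minus the Spearman correlation
    between sample columns; ``"euclidean-log1p"`` uses Euclidean distance
    between log1p-transformed columns.
    """
    X = am.values
    if metric == "1-spearman":
        D = 1.0 - _spearman_matrix(X.values)
        np.fill_diagonal(D, 0.0)
    elif metric == "euclidean-log1p":
        L = np.log1p(X.values)
        sq = (L[:, :, None] - L[:, None, :]) ** 2
        D = np.sqrt(sq.sum(axis=0))
    else:
        raise ValueError("metric must be '1-spearman' or 'euclidean-log1p'")
    return pd.DataFrame(D, index=X.columns, columns=X.columns)


def classical_mds(dissimilarity: pd.DataFrame, k: int = 3) -> OrdinationResult:
    """Torgerson scaling: embed samples so distances approximate ``dissimilarity``.

    Double-centers -D^2/2, takes the top-k eigenpairs and scales the
    eigenvectors by the square roots of their eigenvalues. Negative
    eigenvalues among the top k (non-Euclidean input) are truncated to zero
    coordinates with a warning.
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("dissimilarity matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValidationError("dissimilarity matrix must have a zero diagonal")
    if (D < -1e-12).any():
        raise ValidationError("dissimilarities must be non-negative")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, n-1]; got k={k}, n={n}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam = eigval[:k].copy()
    if (lam < -1e-10 * max(1.0, abs(eigval[0]))).any():
        warnings.warn(
            "negative eigenvalues among the top-k dimensions; the input is "
            "not Euclidean-embeddable at this rank — truncating to zero"
        )
    lam = np.clip(lam, 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(lam)
    index = dissimilarity.index if isinstance(dissimilarity, pd.DataFrame) else None
    cols = [f"dim{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=index, columns=cols),
        eigenvalues=eigval,
    )


def average_reference_columns(
    reference: AbundanceMatrix, column_groups: Mapping[str, str]
) -> AbundanceMatrix:
    """Average reference columns sharing a group label (e.g. per cell type).

    Convenience for turning a per-cell reference matrix into per-cell-type
    profiles; the result keeps the input's unit.
    """
    missing = [c for c in reference.column_ids if c not in column_groups]
    if missing:
        raise ValidationError(f"reference columns without a group label: {missing}")
    cols = {}
    for grp in dict.fromkeys(column_groups[c] for c in reference.column_ids):
        members = [c for c in reference.column_ids if column_groups[c] == grp]
        cols[grp] = reference.values[members].mean(axis=1)
    return AbundanceMatrix(pd.DataFrame(cols), reference.unit)
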