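"""Gene-set (GO term) coverage per cell type.

For each gene set and cell type, count the member genes whose donor-mean
expression exceeds a threshold (strictly above 3 RPKM by default) and
normalize the count to a reference cell type's count (cortical neurons by
default). ``normalize_to="total"`` divides by the number of set genes
present in the matrix instead, so both readings of "coverage" are available.
This is a descriptive coverage metric, not an enrichment test.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io import GeneSetCatalog, ValidationError
from .normalization import AbundanceMatrix, Unit

__all__ = ["CoverageTable", "coverage"]


@dataclasses.dataclass
class CoverageTable:
    """Per-term, per-cell-type covered-gene counts and normalized coverage.

    ``normalized`` holds NaN where the denominator (the reference cell
    type's count, or the term total) is zero; such rows are listed in
    ``undefined_terms``.
    """

    counts: pd.DataFrame       # term_id x cell type, int
    normalized: pd.DataFrame   # term_id x cell type, float (NaN = undefined)
    term_total: pd.Series      # genes of the set present in the matrix
    reference: str
    min_expr: float
    undefined_terms: list[str]

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.add_prefix("count_").join(
            self.normalized.add_prefix("norm_")
        )
        out.insert(0, "term_total", self.term_total)
        return out


def coverage(
    mean_rpkm: AbundanceMatrix,
    catalog: GeneSetCatalog,
    min_expr: float = 3.0,
    reference: str = "CN",
    normalize_to: str = "covered",
) -> CoverageTable:
    """Count set genes expressed strictly above ``min_expr`` per cell type.

    covered(t, c) = |{g in set(t) ∩ matrix : mean_rpkm(g, c) > min_expr}|

    and normalized(t, c) = covered(t, c) / covered(t, reference) (the
    default), or / term_total(t) with ``normalize_to="total"``. Terms with
    no gene in the matrix are kept with term_total 0 and a warning.
    """
    mean_rpkm.require_unit(Unit.RPKM)
    if reference not in mean_rpkm.column_ids:
        raise ValidationError(
            f"reference cell type {reference!r} not among columns "
            f"{mean_rpkm.column_ids}"
        )
    if normalize_to not in ("covered", "total"):
        raise ValueError("normalize_to must be 'covered' or 'total'")

    expressed = mean_rpkm.values > min_expr  # strict
    counts_rows, totals, undefined = {}, {}, []
    for gs in catalog:
        present = [g for g in gs.genes if g in expressed.index]
        totals[gs.term_id] = len(present)
        if not present:
            warnings.warn(
                f"gene set {gs.term_id!r} has no gene in the expression matrix"
            )
            counts_rows[gs.term_id] = pd.Series(0, index=expressed.columns)
        else:
            counts_rows[gs.term_id] = expressed.loc[present].sum(axis=0)
    counts = pd.DataFrame(counts_rows).T.astype(int)
    counts.index.name = "term_id"
    term_total = pd.Series(totals, name="term_total")

    if normalize_to == "covered":
        denom = counts[reference]
    else:
        denom = term_total
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = counts.div(denom.replace(0, np.nan), axis=0)
    undefined = list(denom.index[denom == 0])
    return CoverageTable(counts, normalized, term_total, reference, min_expr, undefined)
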