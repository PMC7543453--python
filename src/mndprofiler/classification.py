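"""Argmax classification of panel genes by best-expressing cell type.

The core procedure: floored per-sample RPKM values are averaged over donors
within each cell type, each gene's profile is rescaled so its highest cell
type reads 100%, and the gene is assigned to that cell type. Genes whose
floored expression is zero everywhere are assigned the NOT_DETECTABLE
category. Summaries report category counts and percentages over the whole
panel and within each disease group, where a gene belonging to several
groups is counted once per group but only once overall.

Classification is scale-invariant (only the argmax and ratios matter) and
deterministic: exact ties are broken by the canonical cell-type order and
flagged.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenePanel, SampleSheet, ValidationError
from .normalization import AbundanceMatrix, Unit

__all__ = [
    "NOT_DETECTABLE",
    "CANONICAL_CELL_TYPES",
    "GeneClassification",
    "ClassificationSummary",
    "donor_mean",
    "classify_gene",
    "classify_matrix",
    "classify_panel",
    "summarize",
]

NOT_DETECTABLE = "NOT_DETECTABLE"

#: Cell types of the study design, in the order used for tie-breaking and display:
#: PBMCs, lymphoblasts, fibroblasts, iPSCs, iPSC-derived cortical neurons.
CANONICAL_CELL_TYPES = ("PBMC", "LB", "F", "iPSC", "CN")


def _canonical_order(cell_types: Iterable[str]) -> list[str]:
    """Known cell types in canonical order first, then the rest as given."""
    cts = list(dict.fromkeys(cell_types))
    known = [c for c in CANONICAL_CELL_TYPES if c in cts]
    rest = [c for c in cts if c not in CANONICAL_CELL_TYPES]
    return known + rest


def round1(x: float) -> float:
    """Round half away from zero to one decimal, the convention used in print."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class GeneClassification:
    """One gene's per-cell-type means, relative percentages and category."""

    gene_symbol: str
    mean_rpkm: dict[str, float]
    relative_percent: dict[str, float]  # empty when not detectable
    category: str  # a cell type or NOT_DETECTABLE
    tie: bool = False

    def __post_init__(self) -> None:
        if self.category != NOT_DETECTABLE:
            if abs(self.relative_percent[self.category] - 100.0) > 1e-9:
                raise ValidationError(
                    f"gene {self.gene_symbol!r}: winning cell type must sit at 100%"
                )


@dataclasses.dataclass
class ClassificationSummary:
    """Counts and percentages per category, overall and per disease group."""

    counts: dict[str, int]
    percentages: dict[str, float]
    per_disease: dict[str, tuple[dict[str, int], dict[str, float]]]
    panel_size: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": "ALL", "category": c, "count": n,
             "percent": self.percentages[c], "group_size": self.panel_size}
            for c, n in self.counts.items()
        ]
        for g, (cnt, pct) in self.per_disease.items():
            size = sum(cnt.values())
            rows += [
                {"group": g, "category": c, "count": n, "percent": pct[c],
                 "group_size": size}
                for c, n in cnt.items()
            ]
        return pd.DataFrame(rows)


def donor_mean(am: AbundanceMatrix, sheet: SampleSheet) -> AbundanceMatrix:
    """Average sample columns within each cell type (arithmetic mean over donors).

    Returns an RPKM matrix with one column per cell type, columns in
    canonical order.
    """
    am.require_unit(Unit.RPKM)
    group = sheet.group_of()
    missing = [s for s in am.column_ids if s not in group]
    if missing:
        raise ValidationError(f"samples without sheet annotation: {missing}")
    cols = {}
    for ct in _canonical_order(sheet.cell_types):
        samples = [s for s in am.column_ids if group[s] == ct]
        if not samples:
            raise ValidationError(f"cell type {ct!r} has no samples in the matrix")
        cols[ct] = am.values[samples].mean(axis=1)
    return AbundanceMatrix(pd.DataFrame(cols), Unit.RPKM)


def classify_gene(
    mean_profile: Mapping[str, float], gene_symbol: str = ""
) -> GeneClassification:
    """Assign a gene to its highest-expressing cell type, or NOT_DETECTABLE.

    The profile maps cell type -> mean (floored) RPKM. If every value is
    zero the gene is not detectable and carries no relative percentages;
    otherwise the winner is set to 100% and the rest scaled accordingly.
    Exact ties go to the first cell type in canonical order and are flagged.
    """
    if len(mean_profile) == 0:
        raise ValidationError(f"gene {gene_symbol!r}: empty expression profile")
    order = _canonical_order(mean_profile.keys())
    vals = {ct: float(mean_profile[ct]) for ct in order}
    neg = [ct for ct, v in vals.items() if v < 0]
    if neg:
        raise ValidationError(f"gene {gene_symbol!r}: negative expression in {neg}")
    top = max(vals.values())
    if top == 0.0:
        return GeneClassification(gene_symbol, vals, {}, NOT_DETECTABLE)
    winners = [ct for ct in order if vals[ct] == top]
    rel = {ct: 100.0 * v / top for ct, v in vals.items()}
    return GeneClassification(gene_symbol, vals, rel, winners[0], tie=len(winners) > 1)


def classify_matrix(mean_am: AbundanceMatrix) -> list[GeneClassification]:
    """Classify every gene of a cell-type-mean RPKM matrix."""
    mean_am.require_unit(Unit.RPKM)
    return [
        classify_gene(row.to_dict(), gene_symbol=str(g))
        for g, row in mean_am.values.iterrows()
    ]


def classify_panel(
    mean_am: AbundanceMatrix,
    panel: GenePanel,
    missing: str = "not_detectable",
) -> list[GeneClassification]:
    """Classify exactly the panel's genes against a cell-type-mean matrix.

    Panel genes absent from the expression matrix are assigned
    NOT_DETECTABLE by default (``missing="not_detectable"``) so the category
    counts always partition the panel; pass ``missing="error"`` to reject
    such inputs instead.
    """
    mean_am.require_unit(Unit.RPKM)
    absent = [g for g in panel.gene_symbols if g not in mean_am.values.index]
    if absent and missing == "error":
        raise ValidationError(f"panel genes absent from expression matrix: {absent}")
    out = []
    zeros = {ct: 0.0 for ct in mean_am.column_ids}
    for g in panel.gene_symbols:
        if g in mean_am.values.index:
            out.append(classify_gene(mean_am.values.loc[g].to_dict(), gene_symbol=g))
        else:
            out.append(GeneClassification(g, dict(zeros), {}, NOT_DETECTABLE))
    return out


def classifications_to_frame(classifications: Sequence[GeneClassification]) -> pd.DataFrame:
    """Flatten classifications into a per-gene table for output."""
    cts = _canonical_order(
        ct for c in classifications for ct in c.mean_rpkm.keys()
    )
    rows = []
    for c in classifications:
        row: dict[str, object] = {"gene_symbol": c.gene_symbol, "category": c.category,
                                  "tie": c.tie}
        for ct in cts:
            row[f"mean_rpkm_{ct}"] = c.mean_rpkm.get(ct, np.nan)
            row[f"relative_percent_{ct}"] = c.relative_percent.get(ct, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    classifications: Sequence[GeneClassification], panel: GenePanel
) -> ClassificationSummary:
    """Count categories over the panel, overall and per disease group.

    Percentages are 100 x count / group size, rounded half away from zero to
    one decimal. Multi-group genes count once overall and once in each of
    their groups; category counts always sum to the group's size.
    """
    by_gene = {c.gene_symbol: c for c in classifications}
    if len(by_gene) != len(classifications):
        raise ValidationError("duplicate gene symbols among classifications")
    extra = set(by_gene) - set(panel.gene_symbols)
    if extra:
        raise ValidationError(f"classified genes absent from panel: {sorted(extra)}")
    missing = [g for g in panel.gene_symbols if g not in by_gene]
    if missing:
        raise ValidationError(f"panel genes without classification: {missing}")

    cell_types = _canonical_order(
        ct for c in classifications for ct in c.mean_rpkm.keys()
    )
    categories = cell_types + [NOT_DETECTABLE]

    def count_block(genes: Sequence[str]) -> tuple[dict[str, int], dict[str, float]]:
        counts = {cat: 0 for cat in categories}
        for g in genes:
            counts[by_gene[g].category] += 1
        size = len(genes)
        pct = {
            cat: (round1(100.0 * n / size) if size else 0.0)
            for cat, n in counts.items()
        }
        return counts, pct

    counts, pct = count_block(panel.gene_symbols)
    per_disease = {
        grp: count_block(panel.genes_in_group(grp)) for grp in panel.groups
    }
    return ClassificationSummary(counts, pct, per_disease, len(panel))
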