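"""Relative qPCR quantification: delta-CT, delta-delta-CT and group ANOVA.

CT (threshold cycle) values decrease by one per doubling of template, so
expression ratios are powers of two in CT differences. Each target gene's
replicate-mean CT is normalized against the arithmetic mean of the
housekeeping genes' mean CTs (delta-CT); the cell line with the lowest
delta-CT — i.e. the highest expression — becomes the reference and relative
expression is 2^-(delta-delta-CT), so the reference sits at exactly 1.
Undetected reactions propagate as missing and are never imputed.

Per gene, replicate-level delta-CT values are compared across cell lines by
one-way fixed-effects ANOVA; pairwise comparisons are corrected by Tukey's
HSD (default) or Holm on pooled-variance t-tests, with significance stars
at 0.05 / 0.01 / 0.001 / 0.0001.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classification import _canonical_order
from .io import FormatError, ValidationError

__all__ = [
    "DEFAULT_HOUSEKEEPING",
    "QPCRPlate",
    "RelativeExpressionResult",
    "AnovaResult",
    "read_qpcr_plate",
    "delta_ct",
    "relative_expression",
    "anova_by_gene",
    "significance_stars",
]

DEFAULT_HOUSEKEEPING = ("GAPDH", "TBP")

_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cutoff, stars in _STAR_LEVELS:
        if p < cutoff:
            return stars
    return "ns"


@dataclasses.dataclass
class QPCRPlate:
    """Replicate-level CT records plus the housekeeping gene names.

    ``records`` columns: gene, cell_line, replicate, ct (NaN = not detected).
    """

    records: pd.DataFrame
    housekeeping: tuple[str, ...] = DEFAULT_HOUSEKEEPING

    def __post_init__(self) -> None:
        required = {"gene", "cell_line", "replicate", "ct"}
        missing = required - set(self.records.columns)
        if missing:
            raise FormatError(f"plate missing columns: {sorted(missing)}")
        self.records = self.records.loc[:, ["gene", "cell_line", "replicate", "ct"]].copy()
        self.records["ct"] = pd.to_numeric(self.records["ct"], errors="raise")
        if (self.records["ct"] <= 0).any():
            bad = self.records[self.records["ct"] <= 0].iloc[0]
            raise ValidationError(
                f"non-positive CT for gene {bad['gene']!r}, line {bad['cell_line']!r}"
            )
        dup = self.records.duplicated(subset=["gene", "cell_line", "replicate"])
        if dup.any():
            bad = self.records[dup].iloc[0]
            raise ValidationError(
                f"duplicate replicate index {bad['replicate']} for gene "
                f"{bad['gene']!r}, line {bad['cell_line']!r}"
            )
        self.housekeeping = tuple(self.housekeeping)
        if not self.housekeeping:
            raise ValidationError("at least one housekeeping gene is required")
        lines = set(self.records["cell_line"])
        for hk in self.housekeeping:
            hk_lines = set(self.records.loc[self.records["gene"] == hk, "cell_line"])
            absent = lines - hk_lines
            if absent:
                raise ValidationError(
                    f"housekeeping gene {hk!r} missing for cell line(s) {sorted(absent)}"
                )

    @property
    def cell_lines(self) -> list[str]:
        return _canonical_order(self.records["cell_line"])

    @property
    def target_genes(self) -> list[str]:
        return [
            g for g in dict.fromkeys(self.records["gene"]) if g not in self.housekeeping
        ]


def read_qpcr_plate(
    path, housekeeping: Sequence[str] = DEFAULT_HOUSEKEEPING
) -> QPCRPlate:
    """Read a plate TSV (gene, cell_line, replicate, ct; empty ct = undetected)."""
    df = pd.read_csv(path, sep="\t")
    return QPCRPlate(df, tuple(housekeeping))


def _housekeeping_mean(plate: QPCRPlate, line: str) -> float:
    """Arithmetic mean over housekeeping genes of their replicate-mean CTs."""
    means = []
    for hk in plate.housekeeping:
        sel = plate.records.query("gene == @hk and cell_line == @line")["ct"].dropna()
        if sel.empty:
            return np.nan
        means.append(sel.mean())
    return float(np.mean(means))


def delta_ct(plate: QPCRPlate) -> pd.DataFrame:
    """Per (gene, cell_line) delta-CT with nd/partial flags.

    delta_ct = mean(detected target CT replicates) - housekeeping mean CT.
    A (gene, line) with no detected target replicate is flagged ``nd`` and
    carries NaN; one with some undetected replicates is flagged ``partial``.
    """
    rows = []
    for gene in plate.target_genes:
        for line in plate.cell_lines:
            cts = plate.records.query("gene == @gene and cell_line == @line")["ct"]
            detected = cts.dropna()
            hk = _housekeeping_mean(plate, line)
            if detected.empty or np.isnan(hk):
                rows.append({"gene": gene, "cell_line": line, "delta_ct": np.nan,
                             "n_detected": 0, "flag": "nd"})
                continue
            flag = "partial" if len(detected) < len(cts) else ""
            rows.append({"gene": gene, "cell_line": line,
                         "delta_ct": float(detected.mean()) - hk,
                         "n_detected": int(len(detected)), "flag": flag})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class RelativeExpressionResult:
    """Per (gene, cell_line) delta-CT, delta-delta-CT and relative expression."""

    table: pd.DataFrame  # gene, cell_line, delta_ct, delta_delta_ct, relative, flag
    reference_lines: dict[str, str]  # gene -> reference cell line
    ties: dict[str, bool]

    def relative_of(self, gene: str, line: str) -> float:
        sel = self.table.query("gene == @gene and cell_line == @line")["relative"]
        return float(sel.iloc[0])


def relative_expression(dct: pd.DataFrame) -> RelativeExpressionResult:
    """Delta-delta-CT against each gene's highest-expressing cell line.

    The reference line minimizes delta-CT (maximal expression) and gets
    relative value exactly 1; ties go to the first line in canonical order
    and are flagged. Genes undetected in every line stay all-missing.
    """
    out_rows, refs, ties = [], {}, {}
    for gene, sub in dct.groupby("gene", sort=False):
        defined = sub.dropna(subset=["delta_ct"])
        if defined.empty:
            refs[gene] = ""
            ties[gene] = False
            for _, row in sub.iterrows():
                out_rows.append({**row, "delta_delta_ct": np.nan,
                                 "relative": np.nan, "flag": "nd"})
            continue
        best = defined["delta_ct"].min()
        winners = [
            ln for ln in _canonical_order(sub["cell_line"])
            if ln in set(defined.loc[defined["delta_ct"] == best, "cell_line"])
        ]
        ref = winners[0]
        refs[gene] = ref
        ties[gene] = len(winners) > 1
        for _, row in sub.iterrows():
            if np.isnan(row["delta_ct"]):
                ddct, rel = np.nan, np.nan
            else:
                ddct = row["delta_ct"] - best
                rel = 1.0 if row["cell_line"] == ref else 2.0 ** (-ddct)
            out_rows.append({**row, "delta_delta_ct": ddct, "relative": rel})
    table = pd.DataFrame(out_rows)
    table["reference_line"] = table["gene"].map(refs)
    return RelativeExpressionResult(table, refs, ties)


def replicate_delta_ct(plate: QPCRPlate) -> pd.DataFrame:
    """Replicate-level delta-CT (each target replicate minus the line's
    housekeeping mean), the inputs for the per-gene ANOVA."""
    rows = []
    for gene in plate.target_genes:
        for line in plate.cell_lines:
            hk = _housekeeping_mean(plate, line)
            cts = plate.records.query("gene == @gene and cell_line == @line")
            for _, r in cts.dropna(subset=["ct"]).iterrows():
                rows.append({"gene": gene, "cell_line": line,
                             "replicate": r["replicate"], "delta_ct": r["ct"] - hk})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class AnovaResult:
    """One gene's one-way ANOVA plus corrected pairwise comparisons."""

    gene: str
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # line_a, line_b, p_corrected, stars
    method: str


def _pairwise_tukey(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    res = stats.tukey_hsd(*groups.values())
    names = list(groups)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        p = float(res.pvalue[i, j])
        rows.append({"line_a": names[i], "line_b": names[j], "p_corrected": p,
                     "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def _pairwise_holm(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    pairs, raw = [], []
    for i, j in itertools.combinations(range(len(names)), 2):
        t = stats.ttest_ind(groups[names[i]], groups[names[j]], equal_var=True)
        pairs.append((names[i], names[j]))
        raw.append(float(t.pvalue))
    corrected = multipletests(raw, method="holm")[1]
    return pd.DataFrame(
        [{"line_a": a, "line_b": b, "p_corrected": float(p),
          "stars": significance_stars(float(p))}
         for (a, b), p in zip(pairs, corrected)]
    )


def anova_by_gene(
    replicate_dct: pd.DataFrame, correction: str = "tukey"
) -> list[AnovaResult]:
    """One-way ANOVA of replicate delta-CT across cell lines, per gene.

    Requires >= 2 cell lines with >= 2 detected replicates each; other lines
    are dropped from the test. If every group has zero within-group variance
    and identical means the statistic is undefined — F is reported as 0 and
    p as 1 with a warning.
    """
    if correction not in ("tukey", "holm"):
        raise ValueError("correction must be 'tukey' or 'holm'")
    results = []
    for gene, sub in replicate_dct.groupby("gene", sort=False):
        groups = {
            line: g["delta_ct"].values.astype(float)
            for line, g in sub.groupby("cell_line", sort=False)
            if len(g) >= 2
        }
        if len(groups) < 2:
            raise ValidationError(
                f"gene {gene!r}: need >= 2 cell lines with >= 2 replicates"
            )
        values = list(groups.values())
        grand = np.concatenate(values)
        if np.allclose(grand, grand[0]):
            warnings.warn(f"gene {gene!r}: all delta-CT values identical; p set to 1")
            f, p = 0.0, 1.0
            pairwise = pd.DataFrame(
                [{"line_a": a, "line_b": b, "p_corrected": 1.0, "stars": "ns"}
                 for a, b in itertools.combinations(groups, 2)]
            )
        else:
            f, p = stats.f_oneway(*values)
            f, p = float(f), float(p)
            pairwise = (
                _pairwise_tukey(groups) if correction == "tukey"
                else _pairwise_holm(groups)
            )
        results.append(AnovaResult(gene, f, p, pairwise, correction))
    return results
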