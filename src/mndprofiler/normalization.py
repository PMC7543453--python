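"""Depth and length normalization of read counts: RPKM, TPM, detection floor.

RPKM (reads per kilobase of transcript per million mapped reads) divides each
count first by the sample's total reads in millions, then by the gene length
in kilobases. TPM (transcripts per million) length-normalizes first and then
scales each sample so its column sums to 10^6, which makes samples directly
comparable as relative molar abundances. Within a sample the two units differ
only by a positive scale factor, so any rank-based downstream step is
indifferent to the choice.

The detection floor zeroes RPKM values strictly below a threshold
(default 0.5); values at the threshold survive. Genes floored to zero in
every sample are later treated as not detectable.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd

from .io import CountMatrix, ValidationError

__all__ = ["Unit", "AbundanceMatrix", "UnitError", "rpkm", "tpm", "apply_detection_floor"]


class Unit(str, enum.Enum):
    RPKM = "RPKM"
    TPM = "TPM"
    RELATIVE_PERCENT = "RELATIVE_PERCENT"
    CT = "CT"
    LOG10_LFQ = "LOG10_LFQ"


class UnitError(ValueError):
    """An operation received an AbundanceMatrix in the wrong unit."""


@dataclasses.dataclass
class AbundanceMatrix:
    """Genes x columns matrix of expression values tagged with its unit.

    Columns are samples or cell types depending on the pipeline stage.
    RPKM/TPM/relative-percent values must be non-negative and complete;
    CT and log10-LFQ matrices may carry NaN as a missing-value marker.
    """

    values: pd.DataFrame
    unit: Unit

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        if self.unit in (Unit.RPKM, Unit.TPM, Unit.RELATIVE_PERCENT):
            if self.values.isna().any().any():
                raise ValidationError(f"{self.unit.value} matrix contains missing values")
            if (self.values.values < 0).any():
                raise ValidationError(f"{self.unit.value} matrix contains negative values")

    def require_unit(self, unit: Unit) -> None:
        if self.unit != Unit(unit):
            raise UnitError(f"expected unit {Unit(unit).value}, got {self.unit.value}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.values.columns)


def rpkm(cm: CountMatrix) -> AbundanceMatrix:
    """Reads per kilobase million.

    value(g, s) = count(g, s) / (total(s) / 10^6) / (length(g) / 1000)

    The library size is the column total of the supplied matrix. Samples
    with zero total reads are rejected.
    """
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"sample(s) with zero total reads: {list(zero.index)}")
    per_million = cm.counts.div(totals / 1e6, axis=1)
    values = per_million.div(cm.gene_lengths / 1000.0, axis=0)
    return AbundanceMatrix(values.astype(float), Unit.RPKM)


def tpm(cm: CountMatrix) -> AbundanceMatrix:
    """Transcripts per million: length-normalize, then scale columns to 10^6."""
    rate = cm.counts.div(cm.gene_lengths / 1000.0, axis=0)
    rate_sum = rate.sum(axis=0)
    zero = rate_sum[rate_sum == 0]
    if len(zero):
        raise ValidationError(
            f"sample(s) with zero total length-normalized rate: {list(zero.index)}"
        )
    values = rate.div(rate_sum, axis=1) * 1e6
    return AbundanceMatrix(values.astype(float), Unit.TPM)


def apply_detection_floor(am: AbundanceMatrix, floor: float = 0.5) -> AbundanceMatrix:
    """Zero RPKM values strictly below ``floor``; keep everything else.

    Idempotent and monotone: applying it twice is the same as once, and no
    value ever increases.
    """
    am.require_unit(Unit.RPKM)
    if floor < 0:
        raise ValueError(f"floor must be >= 0, got {floor}")
    values = am.values.where(am.values >= floor, 0.0)
    return AbundanceMatrix(values, Unit.RPKM)
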