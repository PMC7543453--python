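"""End-to-end orchestration and report aggregation.

``run_all`` wires the stages together — normalize, floor, donor-average,
classify, summarize, then optionally gene-set coverage, reference
similarity with group tests, sample ordination and qPCR analysis — from a
single JSON run configuration, and writes every numeric table plus a
machine-readable ``summary.json``. Outputs are deterministic: the same
config and inputs produce byte-identical files.

``aggregate_replicates`` is the display-table helper that averages
technical replicates per group, optionally on a log10 scale (the convention
for label-free quantification intensities from proteomics).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .classification import (
    classifications_to_frame,
    classify_panel,
    donor_mean,
    summarize,
)
from .coverage import coverage
from .normalization import AbundanceMatrix, Unit, apply_detection_floor, rpkm, tpm
from .qpcr import anova_by_gene, delta_ct, read_qpcr_plate, relative_expression, replicate_delta_ct
from .similarity import (
    classical_mds,
    group_significance,
    sample_dissimilarity,
    spearman_similarity,
)

__all__ = ["RunConfig", "aggregate_replicates", "run_all"]

logger = logging.getLogger("mndprofiler")

SUMMARY_SCHEMA_VERSION = 1


def _sig6(x: float) -> float:
    """Floats in summary.json are serialized at 6 significant digits."""
    return float(f"{float(x):.6g}")


def aggregate_replicates(
    values: Mapping[str, Sequence[float]], transform: str = "none"
) -> pd.DataFrame:
    """Mean per group of replicate measurements, optionally log10-transformed.

    Missing values (NaN) are dropped, with a per-group completeness count;
    log10 of a non-positive value is an error naming the group.
    """
    if transform not in ("none", "log10"):
        raise ValueError("transform must be 'none' or 'log10'")
    rows = []
    for group, vals in values.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size == 0:
            raise eio.ValidationError(f"group {group!r} has no values")
        kept = arr[~np.isnan(arr)]
        if transform == "log10":
            if (kept <= 0).any():
                raise eio.ValidationError(
                    f"group {group!r}: log10 of non-positive value "
                    f"{kept[kept <= 0][0]}"
                )
            kept = np.log10(kept)
        rows.append({
            "group": group,
            "mean": float(kept.mean()) if kept.size else np.nan,
            "n_used": int(kept.size),
            "n_missing": int(arr.size - kept.size),
        })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run."""

    counts: str
    lengths: str
    samples: str
    panel: str
    gmt: str | None = None
    reference: str | None = None
    qpcr_plate: str | None = None
    housekeeping: tuple[str, ...] = ("GAPDH", "TBP")
    floor: float = 0.5
    floor_stage: str = "sample"  # floor per sample before donor averaging, or "mean"
    min_expr: float = 3.0
    reference_cell_type: str = "CN"
    normalize_to: str = "covered"
    background: str = "all"
    correction: str = "tukey"
    mds_k: int = 3
    mds_metric: str = "1-spearman"
    run_similarity: bool = True
    run_mds: bool = True

    def __post_init__(self) -> None:
        for name in ("counts", "lengths", "samples", "panel"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise eio.ValidationError(f"config path {name} does not exist: {p}")
        for name in ("gmt", "reference", "qpcr_plate"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise eio.ValidationError(f"config path {name} does not exist: {p}")
        if self.floor < 0:
            raise eio.ValidationError("floor must be >= 0")
        if self.floor_stage not in ("sample", "mean"):
            raise eio.ValidationError("floor_stage must be 'sample' or 'mean'")
        if self.run_similarity and self.reference is None:
            raise eio.ValidationError(
                "similarity stage enabled but no reference matrix configured"
            )
        self.housekeeping = tuple(self.housekeeping)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(**raw)


def _log_params(cfg: RunConfig) -> None:
    for field in dataclasses.fields(cfg):
        logger.info("parameter %s = %r", field.name, getattr(cfg, field.name))


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute every configured stage and write the report bundle.

    Returns the summary dictionary that is also written to
    ``<outdir>/summary.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _log_params(cfg)

    stage = "input"
    try:
        cm = eio.read_count_matrix(cfg.counts, cfg.lengths)
        sheet = eio.read_sample_sheet(cfg.samples)
        sheet.check_annotates(cm)
        panel = eio.read_panel(cfg.panel)

        stage = "normalize"
        rpkm_am = rpkm(cm)
        tpm_am = tpm(cm)
        if cfg.floor_stage == "sample":
            floored = apply_detection_floor(rpkm_am, cfg.floor)
            means = donor_mean(floored, sheet)
        else:
            means = apply_detection_floor(donor_mean(rpkm_am, sheet), cfg.floor)
        eio.write_table(means.values, outdir / "cell_type_mean_rpkm.tsv",
                        index_label="gene_id")

        stage = "classify"
        classifications = classify_panel(means, panel)
        summary = summarize(classifications, panel)
        eio.write_table(
            classifications_to_frame(classifications).set_index("gene_symbol"),
            outdir / "gene_classification.tsv", index_label="gene_symbol",
        )
        eio.write_table(summary.to_frame().set_index("group"),
                        outdir / "classification_summary.tsv", index_label="group")

        report: dict = {
            "schema_version": SUMMARY_SCHEMA_VERSION,
            "panel_size": summary.panel_size,
            "counts": dict(summary.counts),
            "percentages": {k: _sig6(v) for k, v in summary.percentages.items()},
            "per_disease": {
                g: {"counts": dict(c), "percentages": {k: _sig6(v) for k, v in p.items()}}
                for g, (c, p) in summary.per_disease.items()
            },
            "parameters": {
                "floor": _sig6(cfg.floor),
                "floor_stage": cfg.floor_stage,
                "min_expr": _sig6(cfg.min_expr),
                "reference_cell_type": cfg.reference_cell_type,
                "normalize_to": cfg.normalize_to,
                "background": cfg.background,
                "correction": cfg.correction,
                "mds_metric": cfg.mds_metric,
            },
        }

        if cfg.gmt is not None:
            stage = "coverage"
            catalog = eio.read_gene_sets(cfg.gmt)
            cov = coverage(means, catalog, min_expr=cfg.min_expr,
                           reference=cfg.reference_cell_type,
                           normalize_to=cfg.normalize_to)
            eio.write_table(cov.to_frame(), outdir / "go_coverage.tsv",
                            index_label="term_id")
            report["coverage_terms"] = int(len(cov.counts))

        if cfg.run_similarity and cfg.reference is not None:
            stage = "similarity"
            ref_df = pd.read_csv(cfg.reference, sep="\t", index_col=0)
            reference = AbundanceMatrix(ref_df.astype(float), Unit.TPM)
            sim = spearman_similarity(tpm_am, reference)
            sim = group_significance(sim, sheet.group_of(), background=cfg.background)
            eio.write_table(sim.rho, outdir / "similarity_rho.tsv",
                            index_label="sample_id")
            eio.write_table(sim.group_tests.set_index(["group", "reference"]),
                            outdir / "similarity_tests.tsv")
            report["n_shared_genes"] = int(sim.n_shared_genes)
            top = (sim.group_tests.sort_values("neg_log10_p", ascending=False)
                   .groupby("group", sort=True).head(1))
            report["best_reference_per_group"] = {
                r["group"]: r["reference"] for _, r in top.iterrows()
            }

        if cfg.run_mds:
            stage = "mds"
            D = sample_dissimilarity(tpm_am, metric=cfg.mds_metric)
            ord_res = classical_mds(D, k=min(cfg.mds_k, len(D) - 1))
            eio.write_table(ord_res.coordinates, outdir / "mds_coordinates.tsv",
                            index_label="sample_id")

        if cfg.qpcr_plate is not None:
            stage = "qpcr"
            plate = read_qpcr_plate(cfg.qpcr_plate, cfg.housekeeping)
            dct = delta_ct(plate)
            rel = relative_expression(dct)
            eio.write_table(rel.table.set_index(["gene", "cell_line"]),
                            outdir / "qpcr_relative.tsv")
            anova = anova_by_gene(replicate_delta_ct(plate), correction=cfg.correction)
            rows = []
            for res in anova:
                for _, pw in res.pairwise.iterrows():
                    rows.append({"gene": res.gene, "f_statistic": res.f_statistic,
                                 "anova_p": res.p_value, **pw})
            eio.write_table(pd.DataFrame(rows).set_index("gene"),
                            outdir / "qpcr_anova.tsv", index_label="gene")
            report["qpcr_genes"] = len(anova)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
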