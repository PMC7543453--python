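"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: five cell
types (PBMCs, lymphoblasts, fibroblasts, iPSCs, cortical neurons) from two
donors, a disease-gene panel in which each gene has a planted
best-expressing cell type (or is planted undetectable), a per-cell-type
single-cell-style reference correlated with the bulk generative means,
gene-set catalogs optionally enriched for one cell type's genes, and
triplicate qPCR plates whose CT values encode the planted expression ratios.

Counts are negative-binomial with variance mu + alpha * mu^2 (alpha = 0
degenerates to Poisson): a planted winner's mean is fold_change times the
base mean, undetectable genes are identically zero, and each sample's
expected library size is fixed by rescaling the gene means. Gene lengths
are drawn log-uniformly so RPKM and TPM differ nontrivially. Everything is
reproducible from the config seed.

``canonical_config`` builds the 168-gene fixture whose planted category
distribution, per disease group, matches the study's reported breakdown
(overall: 50 CN, 41 F, 26 LB, 22 iPSC, 14 PBMC, 15 not detectable).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import CANONICAL_CELL_TYPES, NOT_DETECTABLE
from .io import (
    CountMatrix,
    DISEASE_GROUPS,
    GenePanel,
    GeneSet,
    GeneSetCatalog,
    PanelEntry,
    SampleSheet,
    ValidationError,
)
from .normalization import AbundanceMatrix, Unit
from .qpcr import DEFAULT_HOUSEKEEPING, QPCRPlate

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "canonical_config",
    "simulate_counts",
    "simulate_reference",
    "simulate_go_catalog",
    "simulate_qpcr",
]

#: Planted per-category counts for each disease group of the canonical
#: 168-gene fixture, in cell-type order (PBMC, LB, F, iPSC, CN, ND).
CANONICAL_BREAKDOWN: dict[str, dict[str, int]] = {
    "HSP": {"PBMC": 3, "LB": 10, "F": 19, "iPSC": 2, "CN": 26, NOT_DETECTABLE: 5},
    "ALS": {"PBMC": 3, "LB": 6, "F": 5, "iPSC": 5, "CN": 9, NOT_DETECTABLE: 2},
    "SMA": {"PBMC": 1, "LB": 4, "F": 3, "iPSC": 2, "CN": 5, NOT_DETECTABLE: 3},
    "SPASTICITY": {"PBMC": 7, "LB": 6, "F": 14, "iPSC": 13, "CN": 10,
                   NOT_DETECTABLE: 5},
}


@dataclasses.dataclass
class SimulationConfig:
    """Generative parameters for the synthetic study.

    ``planted_categories`` fixes each gene's best-expressing cell type (or
    NOT_DETECTABLE); left as None, categories are drawn uniformly from the
    cell types plus NOT_DETECTABLE. ``library_size`` is each sample's
    expected total read count.
    """

    n_genes: int = 168
    cell_types: tuple[str, ...] = CANONICAL_CELL_TYPES
    donors: int = 2
    planted_categories: tuple[str, ...] | None = None
    base_mean: float = 100.0
    fold_change: float = 10.0
    nb_dispersion: float = 0.1
    library_size: float = 2_000_000.0
    length_range: tuple[int, int] = (500, 10_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.fold_change <= 1:
            raise ValidationError("fold_change must be > 1")
        if self.library_size <= 0:
            raise ValidationError("library_size must be > 0")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        if self.donors < 1:
            raise ValidationError("donors must be >= 1")
        if self.planted_categories is not None:
            allowed = set(self.cell_types) | {NOT_DETECTABLE}
            bad = set(self.planted_categories) - allowed
            if bad:
                raise ValidationError(f"unknown planted categories: {sorted(bad)}")
            if len(self.planted_categories) != self.n_genes:
                raise ValidationError(
                    "planted_categories length must equal n_genes"
                )


@dataclasses.dataclass
class GroundTruth:
    """What was planted: per-gene category and groups, lengths, reference map."""

    planted_category: pd.Series            # gene -> cell type or NOT_DETECTABLE
    disease_groups: dict[str, frozenset[str]]
    gene_lengths: pd.Series
    reference_assignment: dict[str, str]   # bulk group -> reference column
    go_memberships: dict[str, frozenset[str]] = dataclasses.field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.planted_category.index)

    def to_panel(self) -> GenePanel:
        """The synthetic disease-gene panel (HSP genes carry SPG-style aliases)."""
        entries, spg = [], 0
        for g in self.gene_ids:
            groups = self.disease_groups[g]
            alias = None
            if "HSP" in groups:
                spg += 1
                alias = f"SPG{spg}"
            entries.append(PanelEntry(g, alias, groups))
        return GenePanel(entries)


def canonical_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The 168-gene fixture matching the study's planted category breakdown."""
    planted: list[str] = []
    for grp in DISEASE_GROUPS:
        for cat, n in CANONICAL_BREAKDOWN[grp].items():
            planted.extend([cat] * n)
    defaults = dict(
        n_genes=len(planted),
        planted_categories=tuple(planted),
        fold_change=10.0,
        nb_dispersion=0.1,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def _canonical_disease_groups() -> list[frozenset[str]]:
    groups: list[frozenset[str]] = []
    for grp in DISEASE_GROUPS:
        n = sum(CANONICAL_BREAKDOWN[grp].values())
        groups.extend([frozenset([grp])] * n)
    return groups


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i + 1:03d}" for i in range(n)]


def _mean_matrix(cfg: SimulationConfig, planted: Sequence[str]) -> pd.DataFrame:
    """Unscaled per-cell-type expected counts implied by the planted labels."""
    genes = _gene_ids(cfg.n_genes)
    m = pd.DataFrame(cfg.base_mean, index=genes, columns=list(cfg.cell_types))
    for g, cat in zip(genes, planted):
        if cat == NOT_DETECTABLE:
            m.loc[g] = 0.0
        else:
            m.loc[g, cat] = cfg.base_mean * cfg.fold_change
    return m


def simulate_counts(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, SampleSheet, GroundTruth]:
    """Draw the bulk count matrix, its sample sheet and the ground truth."""
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)

    if cfg.planted_categories is not None:
        planted = list(cfg.planted_categories)
    else:
        options = list(cfg.cell_types) + [NOT_DETECTABLE]
        planted = list(rng.choice(options, size=cfg.n_genes))

    lo, hi = cfg.length_range
    lengths = np.rint(
        10 ** rng.uniform(np.log10(lo), np.log10(hi), size=cfg.n_genes)
    ).astype(np.int64)
    gene_lengths = pd.Series(lengths, index=genes)

    means = _mean_matrix(cfg, planted)
    cols, sheet_rows = {}, []
    for ct in cfg.cell_types:
        mu_ct = means[ct].values
        total = mu_ct.sum()
        if total == 0:
            raise ValidationError(
                f"cell type {ct!r} has zero total expected expression"
            )
        mu = mu_ct * (cfg.library_size / total)
        for donor in range(1, cfg.donors + 1):
            sample = f"{ct}_D{donor}"
            if cfg.nb_dispersion == 0:
                counts = rng.poisson(mu)
            else:
                r = 1.0 / cfg.nb_dispersion
                p = r / (r + mu)  # p = 1 where mu = 0 -> counts identically 0
                counts = rng.negative_binomial(r, p)
            cols[sample] = counts
            sheet_rows.append(
                {"sample_id": sample, "donor_id": f"D{donor}", "cell_type": ct}
            )

    cm = CountMatrix(
        counts=pd.DataFrame(cols, index=genes, dtype=np.int64),
        gene_lengths=gene_lengths,
    )
    sheet = SampleSheet(pd.DataFrame(sheet_rows))

    if cfg.planted_categories is not None and cfg.n_genes == 168 and list(
        cfg.planted_categories
    ) == [c for grp in DISEASE_GROUPS
          for cat, n in CANONICAL_BREAKDOWN[grp].items() for c in [cat] * n]:
        disease_groups = dict(zip(genes, _canonical_disease_groups()))
    else:
        cycle = [frozenset([DISEASE_GROUPS[i % len(DISEASE_GROUPS)]])
                 for i in range(cfg.n_genes)]
        disease_groups = dict(zip(genes, cycle))

    truth = GroundTruth(
        planted_category=pd.Series(planted, index=genes),
        disease_groups=disease_groups,
        gene_lengths=gene_lengths,
        reference_assignment={ct: ct for ct in cfg.cell_types},
    )
    return cm, sheet, truth


def generative_tpm_means(cfg: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """The noiseless per-cell-type TPM profiles implied by the generative model."""
    means = _mean_matrix(cfg, list(truth.planted_category))
    rate = means.div(truth.gene_lengths / 1000.0, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def simulate_reference(
    cfg: SimulationConfig,
    truth: GroundTruth,
    rho: float = 0.95,
    seed: int | None = None,
) -> AbundanceMatrix:
    """A per-cell-type TPM reference correlated with the bulk generative means.

    Each reference column mixes the standardized log-profile of the
    matching cell type's generative TPM means with independent Gaussian
    noise at latent correlation ``rho``; rho = 1 reproduces a monotone
    transform of the generative profile exactly.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValidationError(f"reference correlation must be in [-1, 1], got {rho}")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    tpm_means = generative_tpm_means(cfg, truth)
    ref_cols = {}
    for ct in cfg.cell_types:
        latent = np.log1p(tpm_means[ct].values)
        mu, sd = latent.mean(), latent.std()
        sd = sd if sd > 0 else 1.0
        z = (latent - mu) / sd
        noise = rng.standard_normal(len(z))
        mixed = rho * z + np.sqrt(1.0 - rho**2) * noise
        profile = np.clip(np.expm1(mixed * sd + mu), 0.0, None)
        ref_cols[ct] = profile
    ref = pd.DataFrame(ref_cols, index=tpm_means.index)
    col_sums = ref.sum(axis=0)
    if (col_sums == 0).any():
        raise ValidationError("degenerate reference column with zero total")
    ref = ref.div(col_sums, axis=1) * 1e6
    return AbundanceMatrix(ref, Unit.TPM)


def simulate_go_catalog(
    truth: GroundTruth,
    n_terms: int = 5,
    set_size: int = 20,
    enriched_cell_type: str | None = None,
    enrichment: float = 3.0,
    seed: int = 0,
) -> GeneSetCatalog:
    """Random gene sets, optionally enriched for one cell type's planted genes.

    ``enrichment`` is the sampling-weight ratio of the enriched cell type's
    planted genes over the rest; ``enrichment=inf`` draws exclusively from
    them. Membership is recorded in ``truth.go_memberships``.
    """
    if set_size > len(truth.gene_ids):
        raise ValidationError(
            f"set_size {set_size} exceeds number of genes {len(truth.gene_ids)}"
        )
    if enrichment < 1:
        raise ValidationError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    genes = np.array(truth.gene_ids)
    is_target = (
        (truth.planted_category.values == enriched_cell_type)
        if enriched_cell_type is not None
        else np.zeros(len(genes), dtype=bool)
    )
    sets = {}
    for i in range(n_terms):
        term_id = f"TERM{i + 1:03d}"
        if np.isinf(enrichment) and enriched_cell_type is not None:
            pool = genes[is_target]
            if len(pool) < set_size:
                raise ValidationError(
                    f"only {len(pool)} genes planted for {enriched_cell_type!r}; "
                    f"cannot draw a pure set of {set_size}"
                )
            members = rng.choice(pool, size=set_size, replace=False)
        else:
            w = np.where(is_target, enrichment, 1.0)
            members = rng.choice(genes, size=set_size, replace=False, p=w / w.sum())
        members = frozenset(str(g) for g in members)
        sets[term_id] = GeneSet(term_id, f"synthetic gene set {i + 1}", members)
        truth.go_memberships[term_id] = members
    return GeneSetCatalog(sets)


def simulate_qpcr(
    truth: GroundTruth,
    cfg: SimulationConfig,
    genes: Sequence[str] | None = None,
    replicates: int = 3,
    noise_sd: float = 0.15,
    base_ct: float = 30.0,
    housekeeping_ct: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> QPCRPlate:
    """Triplicate CT plates encoding the planted expression ratios.

    CT = base_ct - log2(relative abundance) + Gaussian replicate noise, so a
    planted winner sits fold_change lower in linear expression terms exactly
    log2(fold_change) cycles below the other lines. Housekeeping genes are
    flat across cell lines; planted-undetectable genes yield no CT at all.
    With ``noise_sd=0`` the delta-delta-CT analysis inverts this model
    exactly.
    """
    rng = np.random.default_rng((cfg.seed + 2) if seed is None else seed)
    if genes is None:
        detectable = [g for g in truth.gene_ids
                      if truth.planted_category[g] != NOT_DETECTABLE]
        genes = detectable[: min(10, len(detectable))]
    if housekeeping_ct is None:
        housekeeping_ct = {"GAPDH": 20.0, "TBP": 22.0}
    rows = []
    for gene in genes:
        cat = truth.planted_category[gene]
        for line in cfg.cell_types:
            for rep in range(1, replicates + 1):
                if cat == NOT_DETECTABLE:
                    ct = np.nan
                else:
                    abundance = cfg.fold_change if line == cat else 1.0
                    ct = base_ct - np.log2(abundance) + noise_sd * rng.standard_normal()
                rows.append({"gene": gene, "cell_line": line, "replicate": rep,
                             "ct": ct})
    for hk, level in housekeeping_ct.items():
        for line in cfg.cell_types:
            for rep in range(1, replicates + 1):
                ct = level + noise_sd * rng.standard_normal()
                rows.append({"gene": hk, "cell_line": line, "replicate": rep,
                             "ct": ct})
    return QPCRPlate(pd.DataFrame(rows), tuple(housekeeping_ct))
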