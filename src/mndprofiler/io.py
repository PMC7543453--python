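"""Readers and writers for the tables the pipeline consumes and emits.

All tabular formats are UTF-8 TSV with a header row; gene sets use the GMT
dialect (term_id TAB description TAB gene TAB gene ...). Validation of the
data-model invariants happens here, at the boundary: duplicate identifiers,
negative counts, missing gene lengths and unknown disease-group labels are
rejected with the offending record named, so downstream stages can assume
clean inputs.

Gene identity throughout the package is the gene symbol, matched
case-sensitively after whitespace trimming; the panel's alias column (for
example SPG locus numbers of hereditary spastic paraplegia genes) is carried
along but never used for matching.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "PanelEntry",
    "GenePanel",
    "GeneSet",
    "GeneSetCatalog",
    "DISEASE_GROUPS",
    "FormatError",
    "ValidationError",
    "read_count_matrix",
    "read_sample_sheet",
    "read_panel",
    "read_gene_sets",
    "write_table",
    "write_panel",
    "write_gene_sets",
]

#: Disease groups the panel may reference.
DISEASE_GROUPS = ("HSP", "ALS", "SMA", "SPASTICITY")

#: Format used for every float written by :func:`write_table` (6 significant digits).
FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A well-formed file violates a data-model invariant."""


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in labels:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclasses.dataclass
class CountMatrix:
    """Genes x samples table of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample; integer dtype.
    gene_lengths
        Series mapping every gene id in ``counts`` to its length in base pairs.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        self.counts.index = self.counts.index.astype(str).str.strip()
        self.counts.columns = self.counts.columns.astype(str).str.strip()
        _check_unique(self.counts.index, "gene id")
        _check_unique(self.counts.columns, "sample id")
        if self.counts.isna().any().any():
            bad = self.counts.isna().stack()
            g, s = bad[bad].index[0]
            raise ValidationError(f"missing count for gene {g!r}, sample {s!r}")
        if not all(np.issubdtype(dt, np.integer) for dt in self.counts.dtypes):
            frac = self.counts.astype(float) % 1
            if (frac != 0).any().any():
                bad = (frac != 0).stack()
                g, s = bad[bad].index[0]
                raise ValidationError(
                    f"non-integer count for gene {g!r}, sample {s!r}: "
                    f"{self.counts.loc[g, s]}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any().any():
            bad = (self.counts < 0).stack()
            g, s = bad[bad].index[0]
            raise ValidationError(
                f"negative count for gene {g!r}, sample {s!r}: {self.counts.loc[g, s]}"
            )
        self.gene_lengths = self.gene_lengths.copy()
        self.gene_lengths.index = self.gene_lengths.index.astype(str).str.strip()
        missing = self.counts.index.difference(self.gene_lengths.index)
        if len(missing):
            raise ValidationError(
                f"genes without a length entry: {sorted(missing)}"
            )
        self.gene_lengths = self.gene_lengths.loc[self.counts.index].astype(np.int64)
        if (self.gene_lengths < 1).any():
            bad = self.gene_lengths[self.gene_lengths < 1].index[0]
            raise ValidationError(f"gene {bad!r} has length < 1 bp")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclasses.dataclass
class SampleSheet:
    """Annotation of samples: one row per sample with donor and cell type."""

    table: pd.DataFrame  # columns: sample_id, donor_id, cell_type

    def __post_init__(self) -> None:
        required = {"sample_id", "donor_id", "cell_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        self.table = self.table.loc[:, ["sample_id", "donor_id", "cell_type"]].copy()
        for c in self.table.columns:
            self.table[c] = self.table[c].astype(str).str.strip()
        _check_unique(self.table["sample_id"], "sample id")
        pairs = list(zip(self.table["donor_id"], self.table["cell_type"]))
        _check_unique((f"{d}/{t}" for d, t in pairs), "(donor, cell type) pair")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def cell_types(self) -> list[str]:
        """Cell types in first-appearance order."""
        return list(dict.fromkeys(self.table["cell_type"]))

    def samples_of(self, cell_type: str) -> list[str]:
        m = self.table["cell_type"] == cell_type
        return list(self.table.loc[m, "sample_id"])

    def group_of(self) -> dict[str, str]:
        """Mapping sample id -> cell type."""
        return dict(zip(self.table["sample_id"], self.table["cell_type"]))

    def check_annotates(self, cm: CountMatrix) -> None:
        missing = set(cm.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(
                f"samples in count matrix but not in sample sheet: {sorted(missing)}"
            )


@dataclasses.dataclass(frozen=True)
class PanelEntry:
    gene_symbol: str
    alias: str | None
    disease_groups: frozenset[str]

    def __post_init__(self) -> None:
        if not self.disease_groups:
            raise ValidationError(
                f"panel gene {self.gene_symbol!r} has no disease group"
            )
        unknown = set(self.disease_groups) - set(DISEASE_GROUPS)
        if unknown:
            raise ValidationError(
                f"panel gene {self.gene_symbol!r} has unknown disease group(s) "
                f"{sorted(unknown)}; known: {list(DISEASE_GROUPS)}"
            )


@dataclasses.dataclass
class GenePanel:
    """A disease-gene panel: symbols, optional locus aliases, disease groups.

    A gene may belong to several disease groups (e.g. KIF5A sits in both the
    HSP and ALS groups); the overall panel size counts genes, not
    (gene, group) pairs.
    """

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        _check_unique((e.gene_symbol for e in self.entries), "panel gene symbol")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_symbols(self) -> list[str]:
        return [e.gene_symbol for e in self.entries]

    def genes_in_group(self, group: str) -> list[str]:
        return [e.gene_symbol for e in self.entries if group in e.disease_groups]

    @property
    def groups(self) -> list[str]:
        present = {g for e in self.entries for g in e.disease_groups}
        return [g for g in DISEASE_GROUPS if g in present]


@dataclasses.dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.term_id!r} is empty")


@dataclasses.dataclass
class GeneSetCatalog:
    """Ordered mapping term_id -> GeneSet, as read from a GMT file."""

    sets: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]


# ---------------------------------------------------------------------------
# readers


def read_count_matrix(counts_path: str | Path, lengths_path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus a gene-length TSV.

    The counts file has gene ids in the first column and one column per
    sample; the lengths file has columns ``gene_id`` and ``length_bp``.
    """
    try:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    except Exception as exc:  # malformed beyond repair
        raise FormatError(f"cannot parse counts file {counts_path}: {exc}") from exc
    if counts.shape[1] == 0:
        raise FormatError(f"counts file {counts_path} has no sample columns")
    for col in counts.columns:
        if not np.issubdtype(counts[col].dtype, np.number):
            coerced = pd.to_numeric(counts[col], errors="coerce")
            bad = counts.index[coerced.isna() & counts[col].notna()]
            if len(bad):
                raise ValidationError(
                    f"non-numeric count for gene {bad[0]!r}, sample {col!r}: "
                    f"{counts.loc[bad[0], col]!r}"
                )
            counts[col] = coerced
    lengths = pd.read_csv(lengths_path, sep="\t")
    if not {"gene_id", "length_bp"} <= set(lengths.columns):
        raise FormatError(
            f"lengths file {lengths_path} must have columns gene_id, length_bp"
        )
    _check_unique(lengths["gene_id"].astype(str), "gene id in lengths file")
    length_series = pd.Series(
        lengths["length_bp"].values, index=lengths["gene_id"].astype(str)
    )
    return CountMatrix(counts=counts, gene_lengths=length_series)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", dtype=str))


def read_panel(path: str | Path) -> GenePanel:
    """Read a panel TSV with columns gene_symbol, alias, disease_groups.

    Disease groups are semicolon-separated; an empty alias cell means no alias.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_symbol", "alias", "disease_groups"}
    if not required <= set(df.columns):
        raise FormatError(f"panel file must have columns {sorted(required)}")
    entries = []
    for _, row in df.iterrows():
        symbol = str(row["gene_symbol"]).strip()
        alias = row["alias"]
        alias = None if pd.isna(alias) or str(alias).strip() == "" else str(alias).strip()
        raw = "" if pd.isna(row["disease_groups"]) else str(row["disease_groups"])
        groups = frozenset(g.strip() for g in raw.split(";") if g.strip())
        entries.append(PanelEntry(symbol, alias, groups))
    return GenePanel(entries)


def read_gene_sets(path: str | Path) -> GeneSetCatalog:
    """Read a GMT file: term_id TAB description TAB gene [TAB gene ...]."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term_id, name, *genes = (f.strip() for f in fields)
            genes = [g for g in genes if g]
            if term_id in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            sets[term_id] = GeneSet(term_id, name, frozenset(genes))
    return GeneSetCatalog(sets)


# ---------------------------------------------------------------------------
# writers


def write_table(obj, path: str | Path, index_label: str | None = None) -> None:
    """Write a DataFrame (or Series) as TSV, floats at 6 significant digits."""
    if isinstance(obj, pd.Series):
        obj = obj.to_frame()
    obj.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    rows = [
        {
            "gene_symbol": e.gene_symbol,
            "alias": e.alias or "",
            "disease_groups": ";".join(
                sorted(e.disease_groups, key=DISEASE_GROUPS.index)
            ),
        }
        for e in panel.entries
    ]
    pd.DataFrame(rows, columns=["gene_symbol", "alias", "disease_groups"]).to_csv(
        path, sep="\t", index=False
    )


def write_gene_sets(catalog: GeneSetCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in catalog:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.genes)]) + "\n")
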