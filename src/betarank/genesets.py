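"""Parsing gene-family membership tables and gene lists.

Supports two table dialects out of the box — the Ensembl BioMart paralogue
export (gene ID + family ID columns) and the HGNC (genenames.org) gene
family download (symbol, family, status, locus type) — plus plain gene
lists (one symbol per line, or a CSV with a symbol column).  Column names
drift across database releases, so every reader takes them as arguments
with sensible defaults.

The HGNC reader applies the curation filters used for gene-set size work:
rows whose status is not approved are dropped, RNA locus types (rRNA,
tRNA, microRNA, ...) are dropped, and pseudo-genes are dropped unless
explicitly included.  Pseudo-gene detection is keyed on the locus-type or
status text containing "pseudogene" (case-insensitive).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranked import SizeSample

__all__ = [
    "FamilyTable",
    "ListOverlap",
    "SchemaError",
    "read_ensembl_paralogues",
    "read_hgnc_families",
    "read_gene_list",
    "read_family_pairs",
    "write_family_table",
    "list_counts_per_family",
    "pseudogene_delta",
]

RNA_LOCUS_KEYWORDS = (
    "rna",  # catches "RNA, long non-coding", rRNA, tRNA, microRNA, piRNA, snoRNA ...
)
PSEUDOGENE_KEYWORD = "pseudogene"


class SchemaError(ValueError):
    """Input table lacks required columns (or is empty)."""


@dataclass(frozen=True)
class FamilyTable:
    """Mapping family label -> member gene labels.

    A gene may belong to multiple families (curated sets overlap).
    ``gene_meta`` optionally carries per-gene attributes (status, locus
    type, pseudo-gene flag) indexed by gene label.
    """

    families: dict
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        fam = {str(k): frozenset(str(g) for g in v) for k, v in self.families.items()}
        object.__setattr__(self, "families", fam)

    def __len__(self) -> int:
        return len(self.families)

    def family_sizes(self) -> SizeSample:
        """Family member counts, labelled, in sorted-label order."""
        labels = sorted(self.families)
        sizes = np.asarray([len(self.families[l]) for l in labels], dtype=float)
        return SizeSample(sizes, tuple(labels))

    def genes(self) -> set:
        out: set = set()
        for members in self.families.values():
            out |= members
        return out

    def n_entries(self) -> int:
        """Total (gene, family) memberships, counting multi-membership."""
        return sum(len(v) for v in self.families.values())


def _read_table(table, sep) -> pd.DataFrame:
    try:
        df = pd.read_csv(table, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("empty input table") from exc
    if df.shape[1] == 1 and sep == "\t":
        # tolerate comma-separated files passed through the TSV path
        if isinstance(table, (str, bytes)) or hasattr(table, "read"):
            try:
                if hasattr(table, "seek"):
                    table.seek(0)
                df2 = pd.read_csv(table, sep=",", dtype=str)
                if df2.shape[1] > 1:
                    df = df2
            except Exception:
                pass
    return df


def _require_columns(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}; found {list(df.columns)}")


def read_ensembl_paralogues(
    table,
    gene_col: str = "Gene stable ID",
    family_col: str = "Ensembl Family ID",
    sep: str = "\t",
) -> FamilyTable:
    """Read a BioMart paralogue export: one row per (gene, family).

    Duplicate rows are collapsed; size-1 families are retained here —
    the minimum-size filter belongs to the ranking step.
    """
    df = _read_table(table, sep)
    _require_columns(df, [gene_col, family_col])
    df = df[[gene_col, family_col]].dropna().drop_duplicates()
    if df.empty:
        raise SchemaError("no (gene, family) rows after dropping missing values")
    families: dict[str, set] = {}
    for fam, genes in df.groupby(family_col)[gene_col]:
        families[str(fam)] = set(genes)
    return FamilyTable(families)


def _is_pseudo(row_text: str) -> bool:
    return PSEUDOGENE_KEYWORD in row_text.lower()


def _is_rna(locus: str, keywords=RNA_LOCUS_KEYWORDS) -> bool:
    low = locus.lower()
    if _is_pseudo(low):
        return False  # pseudo-gene rows are handled by the pseudo-gene filter
    return any(k in low for k in keywords)


def read_hgnc_families(
    table,
    include_pseudogenes: bool = False,
    symbol_col: str = "Approved symbol",
    family_col: str = "Gene family ID",
    status_col: str = "Status",
    locus_col: str = "Locus type",
    sep: str = "\t",
    rna_keywords=RNA_LOCUS_KEYWORDS,
) -> FamilyTable:
    """Read an HGNC gene-family table with the curation filters applied.

    Drops non-approved entries and RNA locus types; drops pseudo-genes
    unless ``include_pseudogenes``.  The filters commute, so their order
    is immaterial.
    """
    df = _read_table(table, sep)
    _require_columns(df, [symbol_col, family_col, status_col, locus_col])
    df = df[[symbol_col, family_col, status_col, locus_col]].dropna(subset=[symbol_col, family_col])
    df[status_col] = df[status_col].fillna("")
    df[locus_col] = df[locus_col].fillna("")

    approved = df[status_col].str.lower().str.startswith("approved")
    rna = df[locus_col].map(lambda s: _is_rna(s, rna_keywords))
    pseudo = df[locus_col].map(_is_pseudo) | df[status_col].map(_is_pseudo)
    keep = approved & ~rna
    if not include_pseudogenes:
        keep &= ~pseudo
    df = df[keep].drop_duplicates(subset=[symbol_col, family_col])
    if df.empty:
        raise SchemaError("no gene-family rows survive the curation filters")

    families: dict[str, set] = {}
    for fam, genes in df.groupby(family_col)[symbol_col]:
        families[str(fam)] = set(genes)
    meta = (
        df.rename(columns={symbol_col: "gene", status_col: "status", locus_col: "locus_type"})
        .assign(pseudo=lambda d: d["locus_type"].map(_is_pseudo) | d["status"].map(_is_pseudo))
        .drop_duplicates(subset=["gene"])
        .set_index("gene")[["status", "locus_type", "pseudo"]]
    )
    return FamilyTable(families, meta)


def read_gene_list(source, symbol_col: str | None = None) -> set:
    """Read a gene list: one label per line, or a CSV with ``symbol_col``.

    Labels are whitespace-trimmed and deduplicated; blank lines skipped.
    """
    if symbol_col is not None:
        df = _read_table(source, ",")
        _require_columns(df, [symbol_col])
        labels = {str(x).strip() for x in df[symbol_col].dropna()}
    else:
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source) as fh:
                text = fh.read()
        labels = {line.strip() for line in text.splitlines()}
    labels.discard("")
    if not labels:
        raise ValueError("gene list is empty after trimming")
    return labels


def read_family_pairs(table, gene_col: str = "gene", family_col: str = "family", sep: str = "\t") -> FamilyTable:
    """Read a generic two-column (gene, family) membership table."""
    return read_ensembl_paralogues(table, gene_col=gene_col, family_col=family_col, sep=sep)


def write_family_table(table: FamilyTable, path, gene_col: str = "gene", family_col: str = "family") -> None:
    """Write a FamilyTable as a two-column TSV (round-trips through
    :func:`read_family_pairs`)."""
    rows = [(g, f) for f in sorted(table.families) for g in sorted(table.families[f])]
    pd.DataFrame(rows, columns=[gene_col, family_col]).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ListOverlap:
    """Counts of a gene list's members per family, after a minimum-count
    filter (families with fewer list members than ``min_members`` are
    dropped)."""

    per_family: dict
    list_size: int
    min_members: int

    @property
    def families_retained(self) -> int:
        return len(self.per_family)

    @property
    def genes_covered(self) -> int:
        """Total list-member memberships across retained families (a gene in
        several families counts once per family)."""
        return sum(self.per_family.values())

    def counts_sample(self) -> SizeSample:
        labels = sorted(self.per_family)
        return SizeSample(
            np.asarray([self.per_family[l] for l in labels], dtype=float), tuple(labels)
        )


def list_counts_per_family(families: FamilyTable, genes: set, min_members: int = 2) -> ListOverlap:
    """Cross-tabulate a gene list against a family table.

    Feeds the ranking machinery: the ranked per-family counts of, e.g.,
    transcription factors or drug targets across curated families are
    themselves a rank-size sample.
    """
    if len(families) == 0:
        raise ValueError("family table is empty")
    per_family = {}
    for fam, members in families.families.items():
        c = len(members & genes)
        if c >= min_members:
            per_family[fam] = c
    return ListOverlap(per_family=per_family, list_size=len(genes), min_members=min_members)


def pseudogene_delta(with_pg: FamilyTable, without_pg: FamilyTable) -> pd.DataFrame:
    """Per-family size increase due to including pseudo-genes.

    Returns a frame indexed by family with columns ``size_without`` and
    ``increase``; a family absent from one table counts as size 0 there.
    """
    fams = sorted(set(with_pg.families) | set(without_pg.families))
    rows = []
    for f in fams:
        s_with = len(with_pg.families.get(f, ()))
        s_without = len(without_pg.families.get(f, ()))
        rows.append((f, s_without, s_with - s_without))
    return pd.DataFrame(rows, columns=["family", "size_without", "increase"]).set_index("family")
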