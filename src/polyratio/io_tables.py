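"""Readers and writers for the external table formats the pipeline touches.

Formats owned here:

* HTSeq-count dialect: two-column TSV ``gene_id<TAB>count`` without a
  header; special counter rows beginning with ``__`` (``__no_feature``
  etc.) are ignored on read and never written.
* Gene table TSV (``gene_id, orf_length, site_count``) and count matrix
  TSV (gene_id plus the four library columns).
* TargetScan-style conserved-site table: a headered TSV with at least a
  gene-symbol and a miRNA-family column (an optional site-region
  column); column names are remappable because TargetScan release
  layouts vary.
* GMT gene sets: one set per line, ``name<TAB>description<TAB>member...``.

All readers reject malformed rows with the file and 1-based line number
rather than silently coercing; every dropped row/gene is counted and
logged. Gene symbols are uppercased everywhere — the join key across
counts, site tables and GMT files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .tables import LIBRARIES, CountMatrix, validate_gene_table

__all__ = [
    "GeneSetCollection",
    "TargetSiteRecord",
    "read_counts",
    "write_htseq_counts",
    "read_gene_table",
    "write_gene_table",
    "read_count_matrix",
    "write_count_matrix",
    "read_target_sites",
    "count_sites",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# HTSeq-count two-column dialect
# ---------------------------------------------------------------------------

def _parse_htseq(path) -> dict[str, int]:
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            gene, raw = fields
            if gene.startswith("__"):  # HTSeq special counters
                continue
            if not gene:
                raise FormatError(f"{path}:{lineno}: empty gene_id")
            try:
                value = int(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {raw!r}"
                ) from None
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative count {value}")
            key = gene.upper()
            if key in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate gene_id {gene!r}"
                )
            seen[key] = value
    if not seen:
        raise FormatError(f"{path}: no gene records")
    return seen


def read_counts(paths: Sequence, labels: Sequence[str] = LIBRARIES) -> CountMatrix:
    """Read four HTSeq-count files and inner-join them on gene_id.

    Genes missing from any file are dropped (count logged); library
    sizes are the column sums of the joined matrix.
    """
    if len(paths) != 4 or len(labels) != 4:
        raise InputError("read_counts needs exactly 4 paths and 4 labels")
    per_file = [_parse_htseq(p) for p in paths]
    common = set(per_file[0])
    union = set(per_file[0])
    for d in per_file[1:]:
        common &= set(d)
        union |= set(d)
    if not common:
        raise FormatError("no gene_id present in all four count files")
    dropped = len(union) - len(common)
    if dropped:
        logger.info("read_counts: dropped %d gene(s) missing from at least "
                    "one file", dropped)
    genes = sorted(common)
    frame = pd.DataFrame(
        {lab: np.array([d[g] for g in genes], dtype=np.int64)
         for lab, d in zip(labels, per_file)},
        index=pd.Index(genes, name="gene_id"),
    )
    frame.columns = list(LIBRARIES)  # canonical order as given
    cm = CountMatrix(frame)
    cm.counts.attrs["n_dropped_join"] = dropped
    return cm


def write_htseq_counts(counts: CountMatrix, directory, prefix: str = "") -> list[Path]:
    """Write one two-column HTSeq-dialect file per library; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for lib in LIBRARIES:
        p = directory / f"{prefix}{lib}.tsv"
        counts.counts[lib].to_csv(p, sep="\t", header=False)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Gene table and count matrix TSV
# ---------------------------------------------------------------------------

def write_gene_table(genes: pd.DataFrame, path) -> None:
    validate_gene_table(genes)
    genes[["gene_id", "orf_length", "site_count"]].to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise FormatError(f"{path}: cannot parse gene table: {exc}") from exc
    missing = {"gene_id", "orf_length", "site_count"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: gene table missing column(s) {sorted(missing)}")
    for col in ("orf_length", "site_count"):
        if not np.issubdtype(df[col].dtype, np.integer):
            raise FormatError(f"{path}: column {col!r} must be integer")
    try:
        return validate_gene_table(df)
    except InputError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_count_matrix(counts: CountMatrix, path) -> None:
    counts.counts.to_csv(path, sep="\t")


def read_count_matrix(path) -> CountMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse count matrix: {exc}") from exc
    try:
        return CountMatrix(df)
    except InputError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# TargetScan-style conserved site records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetSiteRecord:
    """One predicted conserved binding site: gene symbol, miRNA family,
    optional transcript id and site region (``UTR3`` or ``other``)."""

    gene_symbol: str
    mirna_family: str
    transcript_id: str | None = None
    site_region: str = "UTR3"


#: Default column mapping for the minimal site-table dialect.
DEFAULT_SITE_COLUMNS = {
    "gene_symbol": "gene_symbol",
    "mirna_family": "mirna_family",
    "transcript_id": "transcript_id",  # optional
    "site_region": "site_region",      # optional
}


def read_target_sites(path, columns: dict | None = None) -> list[TargetSiteRecord]:
    """Read a headered TSV of conserved-site predictions.

    ``columns`` remaps logical fields (gene_symbol, mirna_family,
    transcript_id, site_region) to the file's column names; the two
    mandatory fields must resolve. Rows with an empty symbol or family
    are rejected with their line number.
    """
    colmap = dict(DEFAULT_SITE_COLUMNS)
    if columns:
        colmap.update(columns)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse site table: {exc}") from exc
    for logical in ("gene_symbol", "mirna_family"):
        if colmap[logical] not in df.columns:
            raise FormatError(
                f"{path}: missing required column {colmap[logical]!r} "
                f"(for {logical})"
            )
    has_tx = colmap["transcript_id"] in df.columns
    has_region = colmap["site_region"] in df.columns
    syms = df[colmap["gene_symbol"]].tolist()
    fams = df[colmap["mirna_family"]].tolist()
    txs = df[colmap["transcript_id"]].tolist() if has_tx else [None] * len(df)
    regions = df[colmap["site_region"]].tolist() if has_region else ["UTR3"] * len(df)
    records = []
    for i, (sym, fam, tx, region) in enumerate(zip(syms, fams, txs, regions),
                                               start=2):  # 1 header line
        if not isinstance(sym, str) or not sym.strip():
            raise FormatError(f"{path}:{i}: empty gene symbol")
        if not isinstance(fam, str) or not fam.strip():
            raise FormatError(f"{path}:{i}: empty miRNA family")
        if not isinstance(region, str) or not region.strip():
            region = "other"
        records.append(TargetSiteRecord(
            gene_symbol=sym.strip().upper(),
            mirna_family=fam.strip(),
            transcript_id=(tx if isinstance(tx, str) and tx.strip() else None),
            site_region=region.strip(),
        ))
    return records


def count_sites(
    records: Iterable[TargetSiteRecord],
    region_filter: str = "UTR3",
    master_genes: Iterable[str] | None = None,
) -> pd.Series:
    """Per-gene count of *distinct* miRNA families with at least one site
    passing the region filter.

    With ``master_genes`` given, genes absent from the records receive a
    count of 0 and genes outside the master list are excluded.
    """
    fams: dict[str, set[str]] = {}
    for rec in records:
        if region_filter is not None and rec.site_region != region_filter:
            continue
        fams.setdefault(rec.gene_symbol.upper(), set()).add(rec.mirna_family)
    counts = {g: len(s) for g, s in fams.items()}
    if master_genes is not None:
        master = [str(g).upper() for g in master_genes]
        counts = {g: counts.get(g, 0) for g in master}
    out = pd.Series(counts, dtype=np.int64, name="site_count")
    out.index.name = "gene_symbol"
    return out.sort_index()


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions; members are uppercase symbols."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file; members are de-duplicated and uppercased.

    Lines with fewer than three fields or duplicate set names raise
    :class:`FormatError` with the line number.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, members...), got {len(fields)}"
                )
            name, desc, *members = fields
            if not name:
                raise FormatError(f"{path}:{lineno}: empty set name")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            dedup = frozenset(m.strip().upper() for m in members if m.strip())
            if not dedup:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = dedup
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a GMT file (members sorted for reproducibility)."""
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
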