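"""Shared in-memory containers.

Gene attributes travel as a plain :class:`pandas.DataFrame` with columns
``gene_id`` (unique strings), ``orf_length`` (int nucleotides, >= 3) and
``site_count`` (non-negative int: the number of distinct miRNA families
with at least one conserved 3'-UTR site). :func:`validate_gene_table`
enforces the schema.

Counts travel as :class:`CountMatrix`, a genes x 4 integer matrix for the
libraries WT_L, WT_H, MT_L, MT_H plus per-library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["LIBRARIES", "CountMatrix", "validate_gene_table"]

#: Canonical library order: wild-type light/heavy, mutant light/heavy.
LIBRARIES = ("WT_L", "WT_H", "MT_L", "MT_H")


def validate_gene_table(genes: pd.DataFrame, min_orf: int = 3) -> pd.DataFrame:
    """Validate and return a gene-attribute table (copy not taken)."""
    required = {"gene_id", "orf_length", "site_count"}
    missing = required - set(genes.columns)
    if missing:
        raise InputError(f"gene table missing column(s): {sorted(missing)}")
    if len(genes) == 0:
        raise InputError("gene table is empty")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise InputError(f"duplicate gene_id in gene table: {dup!r}")
    if (genes["orf_length"] < min_orf).any():
        raise InputError(f"orf_length below {min_orf} in gene table")
    if (genes["site_count"] < 0).any():
        raise InputError("negative site_count in gene table")
    return genes


@dataclass
class CountMatrix:
    """Raw counts for the four polysome libraries.

    Attributes
    ----------
    counts : DataFrame indexed by gene_id with integer columns
        ``WT_L, WT_H, MT_L, MT_H``.
    lib_sizes : per-library totals, same index as the columns. When
        derived from the data they equal the column sums; when supplied
        externally they must be at least the column sums.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(LIBRARIES):
            raise InputError(
                f"count matrix columns must be {list(LIBRARIES)}, "
                f"got {list(self.counts.columns)}"
            )
        if len(self.counts) == 0:
            raise InputError("count matrix is empty")
        if self.counts.index.duplicated().any():
            raise InputError("duplicate gene_id in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise InputError("counts must be integers")
        if (vals < 0).any():
            raise InputError("counts must be non-negative")
        sums = self.counts.sum(axis=0)
        if self.lib_sizes is None:
            self.lib_sizes = sums.astype(np.int64)
        else:
            self.lib_sizes = pd.Series(self.lib_sizes, index=list(LIBRARIES)).astype(np.int64)
            if (self.lib_sizes <= 0).any():
                raise InputError("lib_sizes must be positive")
            if (sums > self.lib_sizes).any():
                raise InputError("column sums exceed supplied lib_sizes")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def __len__(self) -> int:
        return len(self.counts)

    def aligned_to(self, gene_ids) -> "CountMatrix":
        """Reindex rows to ``gene_ids`` (must all be present)."""
        missing = pd.Index(gene_ids).difference(self.counts.index)
        if len(missing):
            raise InputError(f"count matrix lacks {len(missing)} requested gene(s)")
        return CountMatrix(self.counts.loc[gene_ids], self.lib_sizes)
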