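"""Light/heavy polysome abundance log-ratios and their ORF-length adjustment.

The central derived statistics of the analysis:

raw ratios
    ``raw_wt = log2(WT_L / WT_H)`` and ``raw_mt = log2(MT_L / MT_H)`` on
    pseudocounted counts-per-million, plus the cross-line ratios
    ``log2(MT_H / WT_H)`` and ``log2(MT_L / WT_L)``. Genes below a raw
    count threshold in any of the four libraries are excluded (the
    expression filter); the exclusion count is logged.

ORF-length adjustment
    A longer ORF accommodates more ribosomes and so depresses the
    light/heavy ratio regardless of miRNA regulation. The adjusted ratio
    is the *residual* of a LOESS regression (span 0.75, local quadratic)
    of the raw ratio on log2 ORF length, fit independently for the wild
    type and the DICER1 mutant.

double adjustment
    ``double_adj = adj_wt - adj_mt``: the change in the adjusted ratio
    caused by the loss of mature miRNA production, which cancels
    regulation shared by the two isogenic lines.

A two-predictor LOESS surface (ratio vs log2 ORF length and
log2(site_count + 1)) is provided for inspection of the joint trend.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import FilterError, InputError
from .loess import LoessFit, loess_fit
from .tables import LIBRARIES, CountMatrix, validate_gene_table

__all__ = [
    "compute_ratios",
    "adjust_by_orf",
    "double_adjust",
    "joint_loess_surface",
]

logger = logging.getLogger(__name__)

#: Ratio-table column -> definition, for reference.
RATIO_COLUMNS = {
    "raw_wt": "log2(WT_L / WT_H)",
    "raw_mt": "log2(MT_L / MT_H)",
    "mt_over_wt_h": "log2(MT_H / WT_H)",
    "mt_over_wt_l": "log2(MT_L / WT_L)",
}


def compute_ratios(
    counts: CountMatrix,
    genes: pd.DataFrame,
    min_count: int = 10,
    pseudocount: float = 0.5,
    outlier_iqr_k: float | None = None,
) -> pd.DataFrame:
    """Build the ratio table (raw columns) from counts and gene attributes.

    Abundance is counts-per-million with a pseudocount:
    ``(count + pseudocount) / lib_size * 1e6``; each log-ratio is the log2
    quotient of two abundances. Genes with a raw count below ``min_count``
    in any library are excluded, as are genes absent from either input
    (inner join on gene_id). With ``outlier_iqr_k`` set, genes whose raw
    WT or MT ratio lies beyond ``k * IQR`` outside the quartiles are also
    removed (an optional, logged outlier rule; off by default).

    Returns a DataFrame with columns ``gene_id, log2_orf, site_count,
    raw_wt, raw_mt, mt_over_wt_h, mt_over_wt_l`` and the filter counts in
    ``.attrs``.
    """
    validate_gene_table(genes)
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    common = counts.gene_ids.intersection(pd.Index(genes["gene_id"]))
    if len(common) == 0:
        raise InputError("count matrix and gene table share no gene_id")
    n_unmatched = (len(counts) - len(common)) + (len(genes) - len(common))
    cm = counts.counts.loc[common]
    keep = (cm >= min_count).all(axis=1)
    n_low = int((~keep).sum())
    cm = cm.loc[keep]
    if len(cm) == 0:
        raise FilterError(
            f"expression filter (min_count={min_count}) removed every gene"
        )
    cpm = (cm + pseudocount) / counts.lib_sizes.to_numpy() * 1e6
    gidx = genes.set_index("gene_id").loc[cm.index]
    table = pd.DataFrame(
        {
            "gene_id": cm.index.to_numpy(),
            "log2_orf": np.log2(gidx["orf_length"].to_numpy(dtype=float)),
            "site_count": gidx["site_count"].to_numpy(dtype=np.int64),
            "raw_wt": np.log2(cpm["WT_L"] / cpm["WT_H"]).to_numpy(),
            "raw_mt": np.log2(cpm["MT_L"] / cpm["MT_H"]).to_numpy(),
            "mt_over_wt_h": np.log2(cpm["MT_H"] / cpm["WT_H"]).to_numpy(),
            "mt_over_wt_l": np.log2(cpm["MT_L"] / cpm["WT_L"]).to_numpy(),
        }
    ).reset_index(drop=True)
    n_outlier = 0
    if outlier_iqr_k is not None:
        keep_mask = np.ones(len(table), dtype=bool)
        for col in ("raw_wt", "raw_mt"):
            v = table[col]
            q1, q3 = v.quantile([0.25, 0.75])
            iqr = q3 - q1
            keep_mask &= (v >= q1 - outlier_iqr_k * iqr) & (v <= q3 + outlier_iqr_k * iqr)
        n_outlier = int((~keep_mask).sum())
        table = table.loc[keep_mask].reset_index(drop=True)
        if len(table) == 0:
            raise FilterError("outlier filter removed every gene")
    logger.info(
        "compute_ratios: %d genes kept; dropped %d unmatched, %d below "
        "min_count=%d, %d outliers", len(table), n_unmatched, n_low,
        min_count, n_outlier,
    )
    table.attrs.update(
        n_kept=len(table), n_unmatched=n_unmatched,
        n_low_count=n_low, n_outlier=n_outlier,
        min_count=min_count, pseudocount=pseudocount,
    )
    return table


def adjust_by_orf(table: pd.DataFrame, span: float = 0.75,
                  degree: int = 2) -> pd.DataFrame:
    """Add ``adj_wt`` and ``adj_mt``: residuals of independent LOESS fits
    of each raw ratio on log2 ORF length. The R^2 of each fit is logged
    and stored in ``.attrs``."""
    for col in ("raw_wt", "raw_mt", "log2_orf"):
        if col not in table.columns:
            raise InputError(f"ratio table lacks column {col!r}")
    if len(table) < 30:
        raise InputError("need at least 30 genes for a meaningful LOESS window")
    out = table.copy()
    x = out["log2_orf"].to_numpy()
    fits = {}
    for cell, raw_col, adj_col in (("wt", "raw_wt", "adj_wt"),
                                   ("mt", "raw_mt", "adj_mt")):
        fit = loess_fit(x, out[raw_col].to_numpy(), span=span, degree=degree)
        out[adj_col] = fit.residual
        fits[cell] = fit
        logger.info("adjust_by_orf[%s]: LOESS span=%g degree=%d R^2=%.4f",
                    cell, span, degree, fit.r_squared)
    out.attrs.update(table.attrs)
    out.attrs.update(r2_wt=fits["wt"].r_squared, r2_mt=fits["mt"].r_squared,
                     span=span, degree=degree)
    return out


def double_adjust(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``double_adj = adj_wt - adj_mt`` per gene."""
    for col in ("adj_wt", "adj_mt"):
        if col not in table.columns:
            raise InputError(f"ratio table lacks column {col!r}; "
                             "run adjust_by_orf first")
    out = table.copy()
    out["double_adj"] = out["adj_wt"] - out["adj_mt"]
    out.attrs.update(table.attrs)
    return out


def joint_loess_surface(table: pd.DataFrame, span: float = 0.75,
                        degree: int = 2, value_column: str = "raw_wt") -> LoessFit:
    """Two-predictor LOESS of a ratio column on (log2 ORF length,
    log2(site_count + 1)). Zero-variance predictor columns are dropped,
    so a constant site column reduces exactly to the 1D ORF fit."""
    for col in (value_column, "log2_orf", "site_count"):
        if col not in table.columns:
            raise InputError(f"ratio table lacks column {col!r}")
    if len(table) < 30:
        raise InputError("need at least 30 genes for a meaningful LOESS window")
    X = np.column_stack([
        table["log2_orf"].to_numpy(dtype=float),
        np.log2(table["site_count"].to_numpy(dtype=float) + 1.0),
    ])
    return loess_fit(X, table[value_column].to_numpy(), span=span, degree=degree)
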