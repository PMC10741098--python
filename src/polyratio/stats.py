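"""Group comparisons, dispersion tests, resampling nulls and site-count trends.

These reproduce the analysis logic around the adjusted ratios: the
targeted-vs-untargeted contrast (mRNAs with more than ``high_threshold``
distinct conserved miRNA-family sites versus mRNAs with none), the
variance-ratio comparison of dispersions, an empirical null built from
repeated random same-size gene samples, and per-site-count trend
summaries with a linearity measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, InsufficientDataError

__all__ = [
    "GroupComparison",
    "SamplingNull",
    "TrendLinearity",
    "compare_groups",
    "variance_ratio_test",
    "sampling_null",
    "trend_by_site_count",
    "trend_linearity",
    "orf_length_by_site_count",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample location (t) and dispersion (variance-ratio F) tests.

    ``f_stat`` is ``var(a) / var(b)`` (sample variances, ddof=1); its
    two-sided p-value doubles the smaller F tail, as R's ``var.test``
    does. The t-test is Welch by default (see :func:`compare_groups`).
    """

    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_stat: float
    t_pvalue: float
    f_stat: float
    f_pvalue: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class SamplingNull:
    """Empirical null of group means from random same-size samples.

    ``empirical_p = (1 + #{sample means >= observed}) / (n_samples + 1)``
    (add-one correction).
    """

    n_samples: int
    sample_size: int
    sample_means: np.ndarray = field(repr=False)
    observed_mean: float
    max_sample_mean: float
    empirical_p: float

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "sample_size": self.sample_size,
            "observed_mean": self.observed_mean,
            "max_sample_mean": self.max_sample_mean,
            "empirical_p": self.empirical_p,
        }


class TrendLinearity(NamedTuple):
    slope: float
    intercept: float
    pearson_r: float


def compare_groups(
    values,
    site_counts,
    high_threshold: int = 50,
    equal_var: bool = False,
    group_a_label: str | None = None,
    group_b_label: str = "no site",
) -> GroupComparison:
    """Compare genes above the site-count threshold against zero-site genes.

    Group A: ``site_count > high_threshold``; group B: ``site_count == 0``.
    The t-test is two-sided Welch (unequal variances) by default — the
    dispersion of the two groups demonstrably differs in this analysis —
    with ``equal_var=True`` restoring the pooled-variance Student test.
    The F statistic is the A/B sample-variance ratio with df
    ``(n_a - 1, n_b - 1)`` and a two-sided p-value.
    """
    values = np.asarray(values, dtype=float)
    site_counts = np.asarray(site_counts)
    if values.shape != site_counts.shape:
        raise InputError("values and site_counts lengths differ")
    a = values[site_counts > high_threshold]
    b = values[site_counts == 0]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"comparison groups need n >= 2 (got n_a={len(a)}, n_b={len(b)})"
        )
    t_res = sps.ttest_ind(a, b, equal_var=equal_var)
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    if var_b == 0.0 and var_a == 0.0:
        f_stat, f_p = 1.0, 1.0
    elif var_b == 0.0:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = var_a / var_b
        cdf = sps.f.cdf(f_stat, len(a) - 1, len(b) - 1)
        f_p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    t_stat = float(t_res.statistic)
    t_p = float(t_res.pvalue)
    if var_a == 0.0 and var_b == 0.0 and np.mean(a) == np.mean(b):
        t_stat, t_p = 0.0, 1.0  # identical degenerate groups
    return GroupComparison(
        group_a_label=group_a_label or f"> {high_threshold} sites",
        group_b_label=group_b_label,
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        t_stat=t_stat, t_pvalue=t_p,
        f_stat=float(f_stat), f_pvalue=float(f_p),
    )


def variance_ratio_test(a, b) -> tuple[float, float]:
    """Two-sided variance-ratio F-test between two samples (e.g. the
    adjusted WT vs MT ratio dispersions). Returns ``(f_stat, p_value)``
    with ``f_stat = var(a) / var(b)`` and df ``(n_a - 1, n_b - 1)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("variance-ratio test needs n >= 2 per sample")
    var_a, var_b = np.var(a, ddof=1), np.var(b, ddof=1)
    if var_b == 0.0:
        return (1.0, 1.0) if var_a == 0.0 else (float("inf"), 0.0)
    f = var_a / var_b
    cdf = sps.f.cdf(f, len(a) - 1, len(b) - 1)
    return float(f), float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))


def sampling_null(
    values,
    target_indices,
    n_samples: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> SamplingNull:
    """Empirical null for the mean of a target gene group.

    Draws ``n_samples`` simple random samples *without replacement*, each
    of the target-group size, from the full value vector (the analyzed
    transcriptome, targets included) and records their means. Samples are
    drawn from a sorted copy of the values, which makes the result
    invariant to the input order under a fixed seed; the observed mean
    uses ``target_indices`` against the original order.
    """
    values = np.asarray(values, dtype=float)
    target_indices = np.asarray(target_indices)
    if target_indices.dtype == bool:
        if target_indices.shape != values.shape:
            raise InputError("boolean target mask must match values")
        target_indices = np.flatnonzero(target_indices)
    size = len(target_indices)
    if size == 0:
        raise InputError("target group is empty")
    if size > len(values):
        raise InputError("target group larger than the value vector")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    observed = float(values[target_indices].mean())
    pool = np.sort(values)
    n = len(pool)
    means = np.empty(n_samples)
    for i in range(n_samples):
        means[i] = pool[rng.choice(n, size, replace=False)].mean()
    emp_p = (1.0 + int((means >= observed).sum())) / (n_samples + 1.0)
    return SamplingNull(
        n_samples=n_samples, sample_size=size, sample_means=means,
        observed_mean=observed, max_sample_mean=float(means.max()),
        empirical_p=float(emp_p),
    )


def trend_by_site_count(
    table: pd.DataFrame,
    value_column: str,
    normalize_per_kb: bool = False,
    min_n: int = 1,
) -> pd.DataFrame:
    """Mean of a ratio column by exact binding-site count.

    Returns one row per observed site count with ``site_count``,
    ``x = log2(site_count + 1)``, ``n_genes`` and ``mean_value``; rows
    with fewer than ``min_n`` genes are dropped. With
    ``normalize_per_kb`` the grouping key is instead the decile bin of
    sites per kilobase of ORF (``site_count / (orf_length_kb)``), with
    ``x = log2(mean rate + 1)`` per bin.
    """
    if value_column not in table.columns:
        raise InputError(f"ratio table lacks column {value_column!r}")
    if normalize_per_kb:
        rate = table["site_count"] / (2.0 ** table["log2_orf"] / 1000.0)
        bins = pd.qcut(rate, 10, duplicates="drop")
        grouped = table.assign(_rate=rate).groupby(bins, observed=True)
        out = grouped.agg(
            n_genes=("gene_id", "size"),
            mean_rate=("_rate", "mean"),
            mean_value=(value_column, "mean"),
        ).reset_index(drop=True)
        out.insert(0, "bin", np.arange(len(out)))
        out.insert(1, "x", np.log2(out["mean_rate"] + 1.0))
    else:
        grouped = table.groupby("site_count", observed=True)
        out = grouped.agg(
            n_genes=("gene_id", "size"),
            mean_value=(value_column, "mean"),
        ).reset_index()
        out.insert(1, "x", np.log2(out["site_count"] + 1.0))
    out = out[out["n_genes"] >= min_n].reset_index(drop=True)
    out.attrs["value_column"] = value_column
    return out


def trend_linearity(trend: pd.DataFrame, weighting: str = "none") -> TrendLinearity:
    """Least-squares line and Pearson correlation of the trend rows
    (``mean_value`` on ``x``); ``weighting="by_n"`` weights the line fit
    by each row's gene count. The correlation is of the plain (x, mean)
    pairs in either case."""
    if weighting not in ("none", "by_n"):
        raise InputError("weighting must be 'none' or 'by_n'")
    if len(trend) < 3:
        raise InputError("trend needs at least 3 rows")
    x = trend["x"].to_numpy(dtype=float)
    ymean = trend["mean_value"].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise InputError("degenerate trend: x has zero variance")
    w = trend["n_genes"].to_numpy(dtype=float) if weighting == "by_n" else None
    slope, intercept = np.polyfit(x, ymean, 1,
                                  w=None if w is None else np.sqrt(w))
    r = float(sps.pearsonr(x, ymean).statistic)
    return TrendLinearity(float(slope), float(intercept), r)


def orf_length_by_site_count(genes: pd.DataFrame) -> pd.DataFrame:
    """Mean log2 ORF length per exact binding-site count.

    Returns rows ``site_count, x, n_genes, mean_log2_orf`` with the
    genome-wide mean log2 ORF length (the reference-line value) in
    ``.attrs["genome_mean_log2_orf"]``.
    """
    if len(genes) == 0:
        raise InputError("gene table is empty")
    l2 = np.log2(genes["orf_length"].to_numpy(dtype=float))
    df = pd.DataFrame({"site_count": genes["site_count"].to_numpy(), "l2": l2})
    out = (df.groupby("site_count", observed=True)
             .agg(n_genes=("l2", "size"), mean_log2_orf=("l2", "mean"))
             .reset_index())
    out.insert(1, "x", np.log2(out["site_count"] + 1.0))
    out.attrs["genome_mean_log2_orf"] = float(l2.mean())
    return out
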