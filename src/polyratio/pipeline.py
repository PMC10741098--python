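"""End-to-end orchestration of the synthetic-data analysis.

``run_full_analysis`` chains: simulate -> ratios -> ORF adjustment ->
double adjustment -> targeted-vs-untargeted comparisons (raw and
adjusted) -> sampling null -> site-count trend (+ linearity) ->
optionally gene-set enrichment against generated decoy sets. It is what
the CLI ``all`` subcommand and the acceptance measurements run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import adjust, simulate, stats
from .config import SimulationConfig
from .enrichment import enrich
from .errors import InputError
from .io_tables import GeneSetCollection
from .tables import CountMatrix

__all__ = ["AnalysisResult", "run_full_analysis", "random_gene_sets"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Artifacts of one end-to-end run."""

    config: SimulationConfig
    genes: pd.DataFrame
    counts: CountMatrix
    ratios: pd.DataFrame  # raw + adjusted + double-adjusted columns
    comparison_raw: stats.GroupComparison | None
    comparison_adj: stats.GroupComparison | None
    null: stats.SamplingNull | None
    trend: pd.DataFrame
    trend_linearity: stats.TrendLinearity
    enrichment: pd.DataFrame | None = None


def random_gene_sets(
    universe,
    n_sets: int = 50,
    set_size: int = 50,
    seed: int | np.random.Generator | None = None,
    prefix: str = "RANDOM_SET",
) -> GeneSetCollection:
    """Draw non-informative same-size gene sets from a universe (decoys
    for enrichment calibration and end-to-end demonstration runs)."""
    universe = list(universe)
    if set_size > len(universe):
        raise InputError("set_size exceeds the universe size")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sets = {}
    descriptions = {}
    for i in range(n_sets):
        idx = rng.choice(len(universe), set_size, replace=False)
        name = f"{prefix}_{i:03d}"
        sets[name] = frozenset(universe[j] for j in idx)
        descriptions[name] = "random decoy set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def run_full_analysis(
    config: SimulationConfig,
    min_count: int = 10,
    pseudocount: float = 0.5,
    span: float = 0.75,
    degree: int = 2,
    high_threshold: int = 50,
    n_samples: int = 1000,
    trend_value_column: str = "double_adj",
    linearity_max_count: int | None = 20,
    gene_sets: GeneSetCollection | None = None,
    n_perm: int = 1000,
    min_set_size: int = 5,
    run_enrichment: bool = False,
    wt_extra_shift: np.ndarray | None = None,
) -> AnalysisResult:
    """Simulate one experiment and run the whole analysis on it.

    Seeds: the simulation uses ``config.seed``; the sampling null uses
    ``config.seed + 1`` and enrichment permutations ``config.seed + 2``
    (all below 2**31 for small master seeds).
    """
    genes, counts = simulate.simulate_experiment(config, wt_extra_shift)
    table = adjust.compute_ratios(counts, genes, min_count=min_count,
                                  pseudocount=pseudocount)
    table = adjust.adjust_by_orf(table, span=span, degree=degree)
    table = adjust.double_adjust(table)

    sc = table["site_count"].to_numpy()
    targets = np.flatnonzero(sc > high_threshold)
    if len(targets) >= 2 and (sc == 0).sum() >= 2:
        comparison_raw = stats.compare_groups(table["raw_wt"].to_numpy(), sc,
                                              high_threshold=high_threshold)
        comparison_adj = stats.compare_groups(table["adj_wt"].to_numpy(), sc,
                                              high_threshold=high_threshold)
        null = stats.sampling_null(table["adj_wt"].to_numpy(), targets,
                                   n_samples=n_samples, seed=config.seed + 1)
    else:
        logger.info("run_full_analysis: fewer than 2 genes above the "
                    "%d-site threshold; skipping group comparison and "
                    "sampling null", high_threshold)
        comparison_raw = comparison_adj = None
        null = None
    trend = stats.trend_by_site_count(table, trend_value_column)
    # Summary line fit restricted to low site counts by default: per-count
    # means beyond ~20 sites rest on a handful of genes and only scatter
    # around the trend.
    lin_rows = (trend if linearity_max_count is None
                else trend[trend["site_count"] <= linearity_max_count])
    lin = stats.trend_linearity(lin_rows, weighting="by_n")

    enr = None
    if run_enrichment:
        if gene_sets is None:
            gene_sets = random_gene_sets(table["gene_id"],
                                         seed=config.seed + 3)
        values = pd.Series(table["double_adj"].to_numpy(),
                           index=table["gene_id"])
        enr = enrich(values, gene_sets, min_set_size=min_set_size,
                     n_perm=n_perm, seed=config.seed + 2)

    return AnalysisResult(
        config=config, genes=genes, counts=counts, ratios=table,
        comparison_raw=comparison_raw, comparison_adj=comparison_adj,
        null=null, trend=trend, trend_linearity=lin, enrichment=enr,
    )
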