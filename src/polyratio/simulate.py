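"""Synthetic polysome-profiling experiments with planted, recoverable effects.

The generator is first-class study apparatus, not a test fixture: its
defaults (see :class:`~polyratio.config.SimulationConfig`) define the
reference conditions under which the downstream adjustment and statistics
are exercised. Two stages:

``simulate_gene_attributes``
    draws ORF lengths (log-normal, floored at 150 nt) and conserved
    miRNA binding-site counts (geometric law with exponential tail,
    optionally coupled to ORF length so targeted mRNAs skew long).

``simulate_counts``
    draws the four library counts. Per gene, the *true* light/heavy log2
    ratio is ``orf_curve(log2 ORF) + beta_mirna * log2(sites + 1) +
    N(0, sigma_wt)`` in the wild type and ``orf_curve(log2 ORF) +
    N(0, sigma_mt)`` in the DICER1 mutant; the light-fraction allocation
    share is the inverse logit of that ratio on the natural-log scale
    (``1 / (1 + 2**-rho)``), and counts are negative-binomial around
    ``share x expression``, scaled to the library size.

Randomness: all draws come from generators spawned from the single master
seed via :class:`numpy.random.SeedSequence` (child 0 for gene attributes,
child 1 for counts), in a fixed documented order. Partial re-simulation
with different parameters therefore changes downstream draws; this is a
deliberate reproducibility-over-flexibility trade.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SimulationConfig
from .errors import InputError
from .tables import LIBRARIES, CountMatrix, validate_gene_table

__all__ = [
    "simulate_gene_attributes",
    "simulate_counts",
    "simulate_experiment",
]

#: Shortest ORF the simulator will emit (50 codons).
MIN_ORF_LENGTH = 150


def _rng_children(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    c0, c1 = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(c0), np.random.default_rng(c1)


def simulate_gene_attributes(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-gene ORF lengths and binding-site counts.

    Site counts are geometric on {0, 1, 2, ...}: at zero coupling
    ``P(count = k) = (1 - p) ** k * p`` with ``p = 1 - site_decay``, so
    successive count frequencies decay by the factor ``site_decay``
    (exponential tail). With coupling ``c > 0`` the per-gene success
    probability is ``expit(logit(p) - c * z)`` where ``z`` is the
    standardized log2 ORF length, which raises the expected count of
    long-ORF genes.

    Returns a gene table (``gene_id``, ``orf_length``, ``site_count``).
    """
    rng, _ = _rng_children(config.seed)
    n = config.n_genes
    # draw order: (1) log2 ORF lengths, (2) site counts
    log2_orf = rng.normal(config.orf_log2_mean, config.orf_log2_sd, n)
    orf_length = np.maximum(MIN_ORF_LENGTH, np.rint(2.0 ** log2_orf)).astype(np.int64)
    log2_orf_actual = np.log2(orf_length.astype(float))
    sd = log2_orf_actual.std()
    z = (log2_orf_actual - log2_orf_actual.mean()) / (sd if sd > 0 else 1.0)
    p0 = 1.0 - config.site_decay
    p = expit(logit(p0) - config.site_orf_coupling * z)
    site_count = rng.geometric(p) - 1  # support {0, 1, 2, ...}
    genes = pd.DataFrame(
        {
            "gene_id": np.array([f"G{i:06d}" for i in range(n)]),
            "orf_length": orf_length,
            "site_count": site_count.astype(np.int64),
        }
    )
    return validate_gene_table(genes, min_orf=MIN_ORF_LENGTH)


def true_log_ratios(
    genes: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    wt_extra_shift: np.ndarray | None = None,
    shared_extra_shift: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the latent WT and MT light/heavy log2 ratios (in that order).

    ``wt_extra_shift`` optionally adds a per-gene deterministic shift to
    the true WT ratio (used to spike gene sets for enrichment studies);
    ``shared_extra_shift`` adds a shift to *both* cell lines (a
    miRNA-independent regulatory layer that the WT-minus-MT double
    adjustment is meant to cancel). Neither disturbs the random stream.
    """
    n = len(genes)
    log2_orf = np.log2(genes["orf_length"].to_numpy(dtype=float))
    base = config.orf_curve(log2_orf)
    g = np.log2(genes["site_count"].to_numpy(dtype=float) + 1.0)
    rho_wt = base + config.beta_mirna * g + rng.normal(0.0, config.sigma_wt, n)
    rho_mt = base + rng.normal(0.0, config.sigma_mt, n)
    for name, shift, both in (("wt_extra_shift", wt_extra_shift, False),
                              ("shared_extra_shift", shared_extra_shift, True)):
        if shift is None:
            continue
        shift = np.asarray(shift, dtype=float)
        if shift.shape != (n,):
            raise InputError(f"{name} must align with the gene table")
        rho_wt = rho_wt + shift
        if both:
            rho_mt = rho_mt + shift
    return rho_wt, rho_mt


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha * mu^2.

    alpha below 1e-8 is treated as the Poisson limit.
    """
    mu = np.maximum(mu, 1e-12)
    if alpha < 1e-8:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def simulate_counts(
    genes: pd.DataFrame,
    config: SimulationConfig,
    wt_extra_shift: np.ndarray | None = None,
    shared_extra_shift: np.ndarray | None = None,
) -> CountMatrix:
    """Draw the four-library count matrix for a gene table.

    Draw order (from seed child 1): (1) total expression levels,
    (2) WT ratio noise, (3) MT ratio noise, (4) counts per library in
    WT_L, WT_H, MT_L, MT_H order.
    """
    validate_gene_table(genes)
    _, rng = _rng_children(config.seed)
    n = len(genes)
    expr = 2.0 ** rng.normal(config.base_expr_log2_mean, config.base_expr_log2_sd, n)
    rho_wt, rho_mt = true_log_ratios(genes, config, rng, wt_extra_shift,
                                     shared_extra_shift)
    share_wt = 1.0 / (1.0 + 2.0 ** (-rho_wt))  # inverse logit of rho * ln 2
    share_mt = 1.0 / (1.0 + 2.0 ** (-rho_mt))
    weights = {
        "WT_L": share_wt * expr,
        "WT_H": (1.0 - share_wt) * expr,
        "MT_L": share_mt * expr,
        "MT_H": (1.0 - share_mt) * expr,
    }
    cols = {}
    for lib, size in zip(LIBRARIES, config.lib_sizes):
        w = weights[lib]
        mu = w / w.sum() * float(size)
        cols[lib] = _nb_draw(rng, mu, config.nb_dispersion).astype(np.int64)
    counts = pd.DataFrame(cols, index=pd.Index(genes["gene_id"], name="gene_id"))
    return CountMatrix(counts)  # lib_sizes derived as column sums


def simulate_experiment(
    config: SimulationConfig,
    wt_extra_shift: np.ndarray | None = None,
    shared_extra_shift: np.ndarray | None = None,
) -> tuple[pd.DataFrame, CountMatrix]:
    """Convenience wrapper: gene attributes plus counts for one config."""
    genes = simulate_gene_attributes(config)
    return genes, simulate_counts(genes, config, wt_extra_shift,
                                  shared_extra_shift)
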