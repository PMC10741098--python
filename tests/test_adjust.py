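"""Ratio computation, ORF-length adjustment, double adjustment, joint surface."""

import numpy as np
import pandas as pd
import pytest

from polyratio import (
    SimulationConfig,
    adjust_by_orf,
    compute_ratios,
    double_adjust,
    joint_loess_surface,
    simulate_experiment,
)
from polyratio.errors import FilterError, InputError

from .conftest import toy_count_matrix, toy_gene_table


def make_table(n, rng, site_counts=None):
    """Ratio-table scaffold with raw columns filled by the caller."""
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "log2_orf": np.sort(rng.uniform(8, 13, n)),
        "site_count": site_counts if site_counts is not None else np.zeros(n, int),
        "raw_wt": np.zeros(n),
        "raw_mt": np.zeros(n),
    })


class TestComputeRatios:
    def test_symmetric_counts_give_zero_ratios(self):
        cm = toy_count_matrix({"g1": (10, 10, 10, 10)},
                              lib_sizes=(1000, 1000, 1000, 1000))
        table = compute_ratios(cm, toy_gene_table(ids=["g1"]),
                               min_count=10, pseudocount=0.5)
        for col in ("raw_wt", "raw_mt", "mt_over_wt_h", "mt_over_wt_l"):
            assert table[col].iloc[0] == 0.0

    def test_fourfold_light_excess(self):
        cm = toy_count_matrix({"g1": (40, 10, 10, 10)},
                              lib_sizes=(1000, 1000, 1000, 1000))
        table = compute_ratios(cm, toy_gene_table(ids=["g1"]),
                               min_count=10, pseudocount=0.0)
        assert table["raw_wt"].iloc[0] == pytest.approx(2.0)

    def test_matches_first_principles_recomputation(self, rng):
        n = 100
        counts = {f"g{i}": tuple(rng.integers(10, 5000, 4)) for i in range(n)}
        cm = toy_count_matrix(counts)
        genes = toy_gene_table(ids=list(counts),
                               orf=rng.integers(300, 9000, n),
                               sites=rng.integers(0, 30, n))
        table = compute_ratios(cm, genes, min_count=10, pseudocount=0.5)
        lib = cm.lib_sizes.to_numpy(dtype=float)
        for _, row in table.sample(20, random_state=1).iterrows():
            c = np.array(counts[row["gene_id"]], dtype=float)
            cpm = (c + 0.5) / lib * 1e6
            assert row["raw_wt"] == pytest.approx(np.log2(cpm[0] / cpm[1]), abs=1e-12)
            assert row["raw_mt"] == pytest.approx(np.log2(cpm[2] / cpm[3]), abs=1e-12)
            assert row["mt_over_wt_h"] == pytest.approx(np.log2(cpm[3] / cpm[1]), abs=1e-12)
            assert row["mt_over_wt_l"] == pytest.approx(np.log2(cpm[2] / cpm[0]), abs=1e-12)

    def test_low_count_genes_filtered_and_counted(self):
        cm = toy_count_matrix({"g1": (50, 50, 50, 50), "g2": (50, 3, 50, 50)})
        table = compute_ratios(cm, toy_gene_table(ids=["g1", "g2"]), min_count=10)
        assert table["gene_id"].tolist() == ["g1"]
        assert table.attrs["n_low_count"] == 1

    def test_all_filtered_raises(self):
        cm = toy_count_matrix({"g1": (1, 1, 1, 1)})
        with pytest.raises(FilterError):
            compute_ratios(cm, toy_gene_table(ids=["g1"]), min_count=10)

    def test_disjoint_gene_ids_raise(self):
        cm = toy_count_matrix({"g1": (10, 10, 10, 10)})
        with pytest.raises(InputError):
            compute_ratios(cm, toy_gene_table(ids=["other"]))

    def test_optional_outlier_rule(self, rng):
        n = 200
        counts = {f"g{i}": (100, 100, 100, 100) for i in range(n - 1)}
        counts["gX"] = (100000, 100, 100, 100)  # wild WT ratio
        cm = toy_count_matrix(counts)
        genes = toy_gene_table(ids=list(counts))
        kept = compute_ratios(cm, genes, outlier_iqr_k=3.0)
        assert "gX" not in set(kept["gene_id"])
        assert kept.attrs["n_outlier"] == 1


class TestAdjustByOrf:
    def test_constant_raw_gives_zero_adjusted(self, rng):
        table = make_table(60, rng)
        table["raw_wt"] = 1.7
        table["raw_mt"] = -0.3
        adj = adjust_by_orf(table)
        assert np.max(np.abs(adj["adj_wt"])) < 1e-10
        assert np.max(np.abs(adj["adj_mt"])) < 1e-10

    def test_smooth_trend_fully_removed(self, rng):
        table = make_table(300, rng)
        x = table["log2_orf"]
        table["raw_wt"] = 2.0 - 0.4 * x + 0.01 * x ** 2
        table["raw_mt"] = np.exp(-(x - 10) ** 2 / 8.0)
        adj = adjust_by_orf(table)
        assert np.max(np.abs(adj["adj_wt"])) < 1e-6
        # smooth but non-polynomial: local quadratic tracks it closely but
        # not exactly at span 0.75
        assert np.max(np.abs(adj["adj_mt"])) < 0.05
        assert adj.attrs["r2_wt"] > 0.999

    def test_residual_mean_near_zero_on_noisy_input(self):
        cfg = SimulationConfig(n_genes=6000, seed=21)
        genes, counts = simulate_experiment(cfg)
        table = compute_ratios(counts, genes)
        adj = adjust_by_orf(table)
        for col in ("adj_wt", "adj_mt"):
            raw = adj[col.replace("adj", "raw")]
            assert abs(adj[col].mean()) < 0.01 * raw.std()

    def test_adjustment_sharpens_site_correlation(self):
        """Removing the ORF trend strengthens the correlation between the
        WT ratio and the binding-site load."""
        cfg = SimulationConfig(n_genes=8000, seed=22)
        genes, counts = simulate_experiment(cfg)
        table = adjust_by_orf(compute_ratios(counts, genes))
        g = np.log2(table["site_count"] + 1.0)
        r_raw = np.corrcoef(table["raw_wt"], g)[0, 1]
        r_adj = np.corrcoef(table["adj_wt"], g)[0, 1]
        assert r_adj > r_raw

    def test_requires_minimum_size(self, rng):
        with pytest.raises(InputError):
            adjust_by_orf(make_table(10, rng))


class TestDoubleAdjust:
    def test_identity_and_difference(self, rng):
        table = make_table(40, rng)
        table["adj_wt"] = 1.0
        table["adj_mt"] = -1.0
        out = double_adjust(table)
        assert (out["double_adj"] == 2.0).all()
        table["adj_mt"] = table["adj_wt"]
        assert (double_adjust(table)["double_adj"] == 0.0).all()

    def test_requires_adjusted_columns(self, rng):
        with pytest.raises(InputError):
            double_adjust(make_table(40, rng))

    def test_planted_effect_recovery_gene_level(self):
        """Gene-level OLS of double_adj on log2(sites+1) recovers the
        planted per-unit shift when sites and ORF length are uncoupled."""
        cfg = SimulationConfig(n_genes=20_000, seed=23, beta_mirna=0.5,
                               site_orf_coupling=0.0, sigma_wt=0.3, sigma_mt=0.3)
        genes, counts = simulate_experiment(cfg)
        table = double_adjust(adjust_by_orf(compute_ratios(counts, genes)))
        g = np.log2(table["site_count"] + 1.0)
        slope = np.polyfit(g, table["double_adj"], 1)[0]
        assert slope == pytest.approx(0.5, abs=0.1)

    def test_shared_perturbation_cancels(self):
        """A cell-line-shared, site-independent perturbation leaves the
        double-adjusted slope essentially unchanged."""
        cfg = SimulationConfig(n_genes=10_000, seed=24, site_orf_coupling=0.0,
                               sigma_wt=0.3, sigma_mt=0.3)
        genes = None
        slopes = []
        for perturb in (False, True):
            from polyratio.simulate import simulate_gene_attributes, simulate_counts
            genes = simulate_gene_attributes(cfg)
            shift = None
            if perturb:
                shift = 0.6 * np.sin(np.arange(len(genes)) * 0.37)
            counts = simulate_counts(genes, cfg, shared_extra_shift=shift)
            table = double_adjust(adjust_by_orf(compute_ratios(counts, genes)))
            g = np.log2(table["site_count"] + 1.0)
            slopes.append(np.polyfit(g, table["double_adj"], 1)[0])
        assert abs(slopes[1] - slopes[0]) < 0.02


class TestJointSurface:
    def test_constant_site_column_reduces_to_orf_fit(self, rng):
        table = make_table(200, rng)
        x = table["log2_orf"].to_numpy()
        table["raw_wt"] = np.sin(x) + rng.normal(0, 0.1, 200)
        from polyratio import loess_fit
        fit2 = joint_loess_surface(table)
        fit1 = loess_fit(x, table["raw_wt"].to_numpy())
        assert np.max(np.abs(fit2.fitted - fit1.fitted)) < 1e-8

    def test_noise_free_additive_surface(self, rng):
        n = 2000
        sites = rng.integers(0, 40, n)
        table = make_table(n, rng, site_counts=sites)
        x = table["log2_orf"].to_numpy()
        g = np.log2(sites + 1.0)
        table["raw_wt"] = (1.0 - 0.3 * x) + 0.4 * g
        fit = joint_loess_surface(table, span=0.3)
        assert np.max(np.abs(fit.residual)) < 1e-3

    def test_row_permutation_equivariance(self, rng):
        n = 300
        sites = rng.integers(0, 20, n)
        table = make_table(n, rng, site_counts=sites)
        table["raw_wt"] = rng.normal(size=n)
        fit = joint_loess_surface(table)
        perm = rng.permutation(n)
        fit_p = joint_loess_surface(table.iloc[perm].reset_index(drop=True))
        assert np.allclose(fit_p.fitted, fit.fitted[perm], atol=1e-10)
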