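"""Group tests against integrated-density oracles; resampling null; trends."""

import numpy as np
import pandas as pd
import pytest

from polyratio import (
    SimulationConfig,
    adjust_by_orf,
    compare_groups,
    compute_ratios,
    orf_length_by_site_count,
    sampling_null,
    simulate_experiment,
    simulate_gene_attributes,
    trend_by_site_count,
    trend_linearity,
)
from polyratio.errors import InputError, InsufficientDataError
from polyratio.stats import variance_ratio_test

from .oracles import f_test_oracle, welch_t_oracle


def groups_to_inputs(a, b):
    values = np.concatenate([a, b])
    sites = np.concatenate([np.full(len(a), 60), np.zeros(len(b), int)])
    return values, sites


class TestCompareGroups:
    def test_identical_groups(self):
        v, s = groups_to_inputs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = compare_groups(v, s)
        assert res.t_stat == 0.0
        assert res.f_stat == 1.0

    def test_small_fixture_matches_integration_oracles(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        v, s = groups_to_inputs(a, b)
        res = compare_groups(v, s)
        assert res.f_stat == pytest.approx(1.0 / 3.5, abs=1e-12)
        t_or, t_p_or = welch_t_oracle(a, b)
        f_or, f_p_or = f_test_oracle(a, b)
        assert res.t_stat == pytest.approx(t_or, abs=1e-9)
        assert res.t_pvalue == pytest.approx(t_p_or, abs=1e-6)
        assert res.f_pvalue == pytest.approx(f_p_or, abs=1e-6)

    @pytest.mark.parametrize("na,nb,seed", [(10, 25, 0), (50, 8, 1), (30, 30, 2)])
    def test_random_fixtures_match_oracles(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.3, 1.2, na)
        b = rng.normal(0.0, 0.8, nb)
        v, s = groups_to_inputs(a, b)
        res = compare_groups(v, s)
        _, t_p = welch_t_oracle(a, b)
        _, f_p = f_test_oracle(a, b)
        assert res.t_pvalue == pytest.approx(t_p, abs=1e-6)
        assert res.f_pvalue == pytest.approx(f_p, abs=1e-6)

    def test_student_flag_pools_variance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 2, 10), rng.normal(0, 0.5, 40)
        v, s = groups_to_inputs(a, b)
        welch = compare_groups(v, s, equal_var=False)
        student = compare_groups(v, s, equal_var=True)
        assert welch.t_pvalue != student.t_pvalue

    def test_insufficient_group_raises(self):
        v, s = groups_to_inputs([1.0], [2.0, 3.0])
        with pytest.raises(InsufficientDataError):
            compare_groups(v, s)

    def test_planted_effect_direction(self):
        """Targeted genes end up with the higher mean adjusted WT ratio in
        (nearly) every replicate under the planted positive effect."""
        wins = 0
        for rep in range(15):
            cfg = SimulationConfig(n_genes=6000, seed=100 + rep)
            genes, counts = simulate_experiment(cfg)
            table = adjust_by_orf(compute_ratios(counts, genes))
            res = compare_groups(table["adj_wt"].to_numpy(),
                                 table["site_count"].to_numpy())
            wins += res.mean_a > res.mean_b
        assert wins >= 14

    def test_variance_ratio_helper_matches_oracle(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1.5, 40), rng.normal(0, 1.0, 60)
        f, p = variance_ratio_test(a, b)
        f_or, p_or = f_test_oracle(a, b)
        assert f == pytest.approx(f_or, abs=1e-12)
        assert p == pytest.approx(p_or, abs=1e-6)


class TestSamplingNull:
    def test_observed_below_all_samples_gives_p_one(self, rng):
        values = rng.normal(0, 1, 500)
        values[:10] = -50.0  # target group far below anything
        res = sampling_null(values, np.arange(10), n_samples=1000, seed=1)
        assert res.empirical_p == pytest.approx(1001 / 1001)

    def test_all_identical_values(self):
        res = sampling_null(np.full(100, 2.5), np.arange(7), seed=0)
        assert res.empirical_p == 1.0
        assert res.max_sample_mean == 2.5

    def test_reproducible_and_order_invariant(self, rng):
        values = rng.normal(0, 1, 300)
        idx = rng.choice(300, 25, replace=False)
        res1 = sampling_null(values, idx, seed=7)
        res2 = sampling_null(values, idx, seed=7)
        assert np.array_equal(res1.sample_means, res2.sample_means)
        perm = rng.permutation(300)
        inv = np.empty(300, int)
        inv[perm] = np.arange(300)
        res3 = sampling_null(values[perm], inv[idx], seed=7)
        assert res3.observed_mean == pytest.approx(res1.observed_mean)
        assert np.array_equal(res3.sample_means, res1.sample_means)
        assert res3.empirical_p == res1.empirical_p

    def test_add_one_correction(self, rng):
        values = rng.normal(0, 1, 200)
        values[:5] += 30.0
        res = sampling_null(values, np.arange(5), n_samples=100, seed=2)
        assert res.empirical_p == pytest.approx(1 / 101)

    def test_empty_target_raises(self, rng):
        with pytest.raises(InputError):
            sampling_null(rng.normal(size=10), np.array([], dtype=int))


class TestTrend:
    def trend_table(self, counts, values, orf=None):
        n = len(counts)
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "log2_orf": np.log2(orf) if orf is not None else np.full(n, 10.0),
            "site_count": counts,
            "double_adj": values,
        })

    def test_two_gene_fixture(self):
        tr = trend_by_site_count(self.trend_table([0, 3], [0.1, 0.7]),
                                 "double_adj")
        assert tr["site_count"].tolist() == [0, 3]
        assert tr["n_genes"].tolist() == [1, 1]
        assert tr["mean_value"].tolist() == pytest.approx([0.1, 0.7])
        assert tr["x"].tolist() == pytest.approx([0.0, 2.0])

    def test_all_zero_counts_single_row(self, rng):
        vals = rng.normal(0, 1, 50)
        tr = trend_by_site_count(self.trend_table(np.zeros(50, int), vals),
                                 "double_adj")
        assert len(tr) == 1
        assert tr["mean_value"].iloc[0] == pytest.approx(vals.mean())

    def test_matches_brute_force_group_means(self):
        cfg = SimulationConfig(n_genes=10_000, seed=30)
        genes, counts = simulate_experiment(cfg)
        table = compute_ratios(counts, genes)
        tr = trend_by_site_count(table, "raw_wt")
        assert int(tr["n_genes"].sum()) == len(table)
        for _, row in tr.iloc[::7].iterrows():
            sel = table[table["site_count"] == row["site_count"]]["raw_wt"]
            assert row["n_genes"] == len(sel)
            assert row["mean_value"] == pytest.approx(sel.mean(), abs=1e-12)

    def test_per_kb_variant_bins_rates(self, rng):
        n = 4000
        table = self.trend_table(rng.integers(0, 40, n), rng.normal(0, 1, n),
                                 orf=rng.integers(300, 12000, n))
        tr = trend_by_site_count(table, "double_adj", normalize_per_kb=True)
        assert 2 <= len(tr) <= 10
        assert int(tr["n_genes"].sum()) == n
        assert tr["x"].is_monotonic_increasing

    def test_linearity_collinear_rows(self):
        tr = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0],
                           "mean_value": [1.0, 1.5, 2.0, 2.5],
                           "n_genes": [5, 5, 5, 5]})
        lin = trend_linearity(tr)
        assert lin.pearson_r == pytest.approx(1.0)
        assert lin.slope == pytest.approx(0.5)

    def test_linearity_errors(self):
        tiny = pd.DataFrame({"x": [0.0, 1.0], "mean_value": [0, 1],
                             "n_genes": [1, 1]})
        with pytest.raises(InputError):
            trend_linearity(tiny)
        flat = pd.DataFrame({"x": [1.0, 1.0, 1.0], "mean_value": [0, 1, 2],
                             "n_genes": [1, 1, 1]})
        with pytest.raises(InputError):
            trend_linearity(flat)


class TestOrfLengthBySiteCount:
    def test_two_gene_fixture(self):
        genes = pd.DataFrame({"gene_id": ["a", "b"],
                              "orf_length": [1024, 4096],
                              "site_count": [0, 2]})
        tr = orf_length_by_site_count(genes)
        assert tr["mean_log2_orf"].tolist() == pytest.approx([10.0, 12.0])
        assert tr.attrs["genome_mean_log2_orf"] == pytest.approx(11.0)

    def test_no_coupling_no_trend(self):
        cfg = SimulationConfig(n_genes=30_000, seed=31, site_orf_coupling=0.0)
        genes = simulate_gene_attributes(cfg)
        tr = orf_length_by_site_count(genes)
        gmean = tr.attrs["genome_mean_log2_orf"]
        sd = np.log2(genes["orf_length"]).std()
        big = tr[tr["n_genes"] >= 100]
        se = sd / np.sqrt(big["n_genes"])
        frac_within = (np.abs(big["mean_log2_orf"] - gmean) <= 2 * se).mean()
        assert frac_within >= 0.85  # ~95% expected, allow sampling slack

    def test_coupling_gives_rising_trend(self):
        from scipy.stats import spearmanr
        cfg = SimulationConfig(n_genes=30_000, seed=32, site_orf_coupling=0.8)
        genes = simulate_gene_attributes(cfg)
        tr = orf_length_by_site_count(genes)
        big = tr[tr["n_genes"] >= 50]
        rho = spearmanr(big["site_count"], big["mean_log2_orf"]).statistic
        assert rho > 0.9
        # the running mean crosses the genome-wide mean at a mid count
        gmean = tr.attrs["genome_mean_log2_orf"]
        below = big[big["mean_log2_orf"] < gmean]["site_count"].max()
        assert below >= 1
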