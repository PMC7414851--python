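"""TPM, enrichment, selections, quantile machinery and rank-sum tests."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import replimap as rm
from replimap import profiles as prof


class TestTpm:
    def test_arithmetic(self):
        assert np.allclose(rm.tpm_normalize([1, 1, 2]),
                           [250_000, 250_000, 500_000])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 10_000), min_size=1, max_size=200)
           .filter(lambda c: sum(c) > 0))
    def test_sums_to_one_million(self, counts):
        assert rm.tpm_normalize(counts).sum() == pytest.approx(1e6, rel=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 100, size=50)
        perm = rng.permutation(50)
        assert np.allclose(rm.tpm_normalize(counts)[perm],
                           rm.tpm_normalize(counts[perm]))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            rm.tpm_normalize([0, 0])


class TestEnrichment:
    def test_equal_tracks_give_zero(self):
        t = np.array([5.0, 10.0, 1.0])
        assert np.allclose(rm.compute_enrichment(t, t), 0.0)

    def test_doubling_gives_one_without_pseudocount(self):
        t = np.array([5.0, 10.0, 1.0])
        assert np.allclose(rm.compute_enrichment(2 * t, t, pseudocount=0), 1.0)

    def test_pseudocount_regularises_empty_input(self):
        e = rm.compute_enrichment(np.array([100.0]), np.array([0.0]),
                                  pseudocount=1.0)
        assert e[0] == pytest.approx(math.log2(101.0), abs=1e-12)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="different grids"):
            rm.compute_enrichment(np.ones(3), np.ones(4))

    def test_zero_pseudocount_needs_positive_tracks(self):
        with pytest.raises(ValueError, match="strictly positive"):
            rm.compute_enrichment(np.array([1.0, 0.0]), np.array([1.0, 1.0]),
                                  pseudocount=0)


class TestSelection:
    def test_threshold_is_strict(self):
        assert rm.select_enriched_windows([-1.0, 0.0, 0.5]).tolist() == [2]

    def test_extremes(self):
        assert rm.select_enriched_windows([-1, -2]).size == 0
        assert rm.select_enriched_windows([1, 2, 3]).tolist() == [0, 1, 2]


class TestControls:
    def test_whole_grid(self):
        assert rm.sample_matched_controls(10, 10, seed=0).tolist() == list(range(10))

    def test_deterministic_and_distinct(self):
        a = rm.sample_matched_controls(100, 10, seed=42)
        b = rm.sample_matched_controls(100, 10, seed=42)
        assert np.array_equal(a, b)
        assert len(np.unique(a)) == 10

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            rm.sample_matched_controls(5, 6, seed=0)

    def test_unbiased_mean_rt(self, rt_track):
        """Control sets are random: over 200 seeds their mean RT matches
        the genome-wide mean within 3 standard errors."""
        means = [rt_track[rm.sample_matched_controls(len(rt_track), 50,
                                                     seed=s)].mean()
                 for s in range(200)]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - rt_track.mean()) < 3 * se


class TestQuantiles:
    def test_one_window_per_quantile(self):
        labels = rm.assign_quantiles(np.arange(1, 26), n=25)
        assert labels.tolist() == list(range(1, 26))

    def test_hundred_values(self):
        values = np.arange(1, 101)
        labels = rm.assign_quantiles(values, n=25)
        assert np.bincount(labels)[1:].tolist() == [4] * 25
        assert labels[values == 7][0] == 2

    def test_ties_broken_by_input_order(self):
        values = np.ones(10)
        labels = rm.assign_quantiles(values, n=5)
        # tie order = genomic (input) order, sizes differ by at most 1
        assert labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_remainder_goes_to_lowest_quantiles(self):
        labels = rm.assign_quantiles(np.arange(11), n=3)
        assert np.bincount(labels)[1:].tolist() == [4, 4, 3]

    def test_partition_with_missing_values(self, rt_track):
        values = rt_track.copy()
        values[::7] = np.nan
        labels = rm.assign_quantiles(values, n=25)
        assert (labels[np.isnan(values)] == 0).all()
        sizes = np.bincount(labels)[1:]
        assert sizes.sum() == np.isfinite(values).sum()
        assert sizes.max() - sizes.min() <= 1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            rm.assign_quantiles(np.arange(10), n=25)


class TestQuantileProfile:
    def test_constant_tpm_equal_means(self):
        labels = rm.assign_quantiles(np.arange(100), n=25)
        profile = rm.quantile_coverage_profile(np.full(100, 7.0), labels)
        assert np.allclose(profile.summary["mean"], 7.0)

    def test_monotone_tpm_gives_monotone_means(self):
        values = np.arange(100, dtype=float)
        labels = rm.assign_quantiles(values, n=25)
        profile = rm.quantile_coverage_profile(values * 2, labels)
        assert (np.diff(profile.summary["mean"]) > 0).all()

    def test_membership_partitions_windows(self, rt_track):
        labels = rm.assign_quantiles(rt_track, n=25)
        profile = rm.quantile_coverage_profile(np.ones_like(rt_track), labels)
        all_ids = np.concatenate(list(profile.members.values()))
        assert len(all_ids) == len(rt_track)
        assert len(np.unique(all_ids)) == len(rt_track)


class TestViolinSummary:
    def test_identical_sets(self, rt_track):
        ids = np.arange(40)
        out = rm.violin_rt_summary(ids, ids, rt_track)
        assert out["selected"] == out["controls"]
        assert out["p_value"] == pytest.approx(1.0)

    def test_linear_interpolation_quartiles(self):
        rt = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = rm.violin_rt_summary(np.arange(5), np.arange(5), rt)
        s = out["selected"]
        assert (s["median"], s["q1"], s["q3"]) == (3.0, 2.0, 4.0)

    def test_early_biased_selection_shifts_rt(self, rt_track):
        counts = rm.simulate_chip_counts(rt_track,
                                         rm.SimChipConfig(bias_beta=1.0, seed=1))
        inp = rm.simulate_chip_counts(rt_track,
                                      rm.SimChipConfig(bias_beta=0.0, seed=2))
        enr = rm.compute_enrichment(rm.tpm_normalize(counts),
                                    rm.tpm_normalize(inp))
        sel = rm.select_enriched_windows(enr)
        ctl = rm.sample_matched_controls(len(rt_track), len(sel), seed=1)
        out = rm.violin_rt_summary(sel, ctl, rt_track)
        assert out["selected"]["median"] > out["controls"]["median"]
        assert out["p_value"] < 1e-3


def _mwu_oracle(x, y):
    """Independent brute force: U by direct pairwise comparison, two-sided p
    by enumerating every subset assignment of the pooled values."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)

    def u_of(a, b):
        return sum(1.0 if ai > bj else 0.5 if ai == bj else 0.0
                   for ai in a for bj in b)

    u_obs = u_of(x, y)
    pooled = x + y
    us = []
    for comb in itertools.combinations(range(n + m), n):
        a = [pooled[i] for i in comb]
        b = [pooled[i] for i in range(n + m) if i not in comb]
        us.append(u_of(a, b))
    us = np.array(us)
    p = 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean())
    return u_obs, min(1.0, p)


class TestMannWhitney:
    def test_textbook_separation(self):
        u, p = rm.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = rm.mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0
        _, p = rm.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n,m", [(n, m) for n in range(1, 7)
                                     for m in range(n, 7)])
    def test_exact_branch_equals_enumeration_oracle(self, n, m):
        rng = np.random.default_rng(100 * n + m)
        # integers induce ties, exercising the midrank path
        x = rng.integers(0, 6, size=n).astype(float)
        y = rng.integers(0, 6, size=m).astype(float)
        u, p = rm.mann_whitney_u(x, y, method="exact")
        u_ref, p_ref = _mwu_oracle(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        _, p = rm.mann_whitney_u(x, y, method="exact")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_asymptotic_branches_agree(self):
        """At n = m = 9 the normal approximation with continuity correction
        tracks the exact enumeration within 0.01 across 50 seeds."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=9)
            y = rng.normal(size=9)
            _, p_ex = rm.mann_whitney_u(x, y, method="exact")
            _, p_as = rm.mann_whitney_u(x, y, method="asymptotic")
            assert abs(p_ex - p_as) < 0.01

    def test_null_p_values_uniform(self):
        """Under the null (same distribution both arms) the asymptotic
        p-values are uniform: KS test not rejected at alpha = 0.01."""
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            _, p = rm.mann_whitney_u(rng.normal(size=20), rng.normal(size=20))
            ps.append(p)
        d, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rm.mann_whitney_u([], [1.0])


class TestTrend:
    def _profile_from_means(self, means):
        import pandas as pd
        summary = pd.DataFrame({"quantile": np.arange(1, len(means) + 1),
                                "mean": means})
        return prof.QuantileProfile(scheme="rt", sample="s",
                                    n_quantiles=len(means), summary=summary)

    def test_monotone_extremes(self):
        rho, flat = rm.trend_statistic(self._profile_from_means([1, 2, 3, 4]))
        assert rho == 1.0 and not flat
        rho, _ = rm.trend_statistic(self._profile_from_means([4, 3, 2, 1]))
        assert rho == -1.0

    def test_hand_computed_rho(self):
        rho, _ = rm.trend_statistic(self._profile_from_means([1, 3, 2]))
        assert rho == pytest.approx(0.5)

    def test_constant_means_flagged(self):
        rho, flat = rm.trend_statistic(self._profile_from_means([2, 2, 2]))
        assert rho == 0.0 and flat
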