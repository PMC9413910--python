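"""Window selection, bin compression, and the exact BCS probability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ubcs.core import (
    BinVector,
    ClusterParams,
    binom_from,
    brute_force_prob_bcs,
    compress_to_bins,
    estimate_p_hat,
    generate_bin_frequencies,
    observed_bcs_flags,
    prob_bcs,
    select_representative_windows,
    ubcs_profile,
    ubcs_region,
)
from conftest import make_catalog


def enumerate_windows(positions, focal_index, params):
    """Independent oracle: all distinct window contents over every aligned
    integer start covering the focal position."""
    pos = np.asarray(positions)
    f = int(pos[focal_index])
    contents = {}
    for s in range(max(0, f - params.window_size + 1), f + 1):
        if s % params.start_divisor:
            continue
        l = int(np.searchsorted(pos, s))
        r = int(np.searchsorted(pos, s + params.window_size))
        if r - l >= params.min_cluster and (l, r) not in contents:
            contents[(l, r)] = s
    return contents


def random_instance(rng, max_subs=14):
    n = int(rng.integers(2, max_subs))
    span = int(rng.integers(50, 700))
    pos = np.sort(rng.choice(span, size=min(n, span), replace=False)).astype(np.int64)
    f = int(rng.integers(0, pos.size))
    return pos, f


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window_size": 0},
            {"bias_threshold": 0.0},
            {"bias_threshold": 1.2},
            {"min_cluster": 0},
            {"start_divisor": 7},  # does not divide 300
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ClusterParams(**kwargs)

    @pytest.mark.parametrize(
        "size,threshold,expected",
        [(5, 0.8, 4), (6, 0.8, 5), (10, 0.8, 8), (4, 1.0, 4), (7, 0.5, 4)],
    )
    def test_min_biased_exact_rational(self, size, threshold, expected):
        assert ClusterParams(bias_threshold=threshold).min_biased(size) == expected


class TestSelectWindows:
    def test_isolated_substitution(self, params):
        assert select_representative_windows([5000], 0, params) == []

    def test_too_few_neighbors(self, params):
        # focal plus 3 others within the window span: every window has < 5
        pos = [1000, 1050, 1100, 1150]
        assert select_representative_windows(pos, 1, params) == []

    def test_five_in_one_span_single_representative(self, params):
        pos = [1000, 1010, 1050, 1100, 1150]
        for f in range(5):
            wins = select_representative_windows(pos, f, params)
            assert len(wins) == 1

    def test_matches_enumeration(self, params):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pos, f = random_instance(rng)
            wins = select_representative_windows(pos, f, params)
            oracle = enumerate_windows(pos, f, params)
            assert sorted(wins) == sorted(oracle.values())

    def test_representative_bound(self, params):
        """n never exceeds the substitution count of the covering region."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            pos, f = random_instance(rng)
            wins = select_representative_windows(pos, f, params)
            m = params.window_size
            c = int(
                np.searchsorted(pos, pos[f] + m)
                - np.searchsorted(pos, pos[f] - m + 1)
            )
            assert len(wins) <= c


class TestCompress:
    def test_single_window(self, params):
        pos = [1000, 1010, 1050, 1100, 1150]
        wins = select_representative_windows(pos, 2, params)
        bins = compress_to_bins(wins, pos, 2, params)
        assert bins.bin_sizes == (5,)
        assert bins.n_windows == 1 and bins.focal_bin == 0

    def test_two_windows_three_bins(self, params):
        # six positions spanning > window size: two distinct window contents
        pos = [1000, 1060, 1120, 1180, 1240, 1310]
        wins = select_representative_windows(pos, 3, params)
        assert len(wins) == 2
        bins = compress_to_bins(wins, pos, 3, params)
        assert len(bins.bin_sizes) == 3
        for k, s in enumerate(wins):
            in_window = sum(1 for p in pos if s <= p < s + params.window_size)
            assert bins.cluster_size(k) == in_window

    def test_cluster_sums_and_focal_bin(self, params):
        rng = np.random.default_rng(13)
        checked = 0
        for _ in range(200):
            pos, f = random_instance(rng)
            wins = select_representative_windows(pos, f, params)
            if not wins:
                continue
            bins = compress_to_bins(wins, pos, f, params)
            assert len(bins.bin_sizes) == 2 * bins.n_windows - 1
            assert bins.bin_sizes[bins.focal_bin] >= 1
            for k, s in enumerate(sorted(wins)):
                count = sum(1 for p in pos if s <= p < s + params.window_size)
                assert bins.cluster_size(k) == count >= params.min_cluster
            checked += 1
        assert checked > 50


class TestBinomFrom:
    @pytest.mark.parametrize(
        "bin_size,start,p,expected",
        [(5, 0, 0.3, 1.0), (3, 4, 0.9, 0.0), (5, 4, 0.5, 0.1875), (5, -1, 0.2, 1.0)],
    )
    def test_examples(self, bin_size, start, p, expected):
        assert binom_from(bin_size, start, p) == pytest.approx(expected, abs=1e-12)

    def test_against_scipy_tail(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            b = int(rng.integers(0, 15))
            k = int(rng.integers(0, b + 2))
            p = float(rng.uniform(0, 1))
            assert binom_from(b, k, p) == pytest.approx(
                stats.binom.sf(k - 1, b, p), abs=1e-10
            )

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            binom_from(5, 2, 1.5)


class TestGenerateBinFrequencies:
    def test_single_bernoulli_bin(self):
        assert generate_bin_frequencies([1], 0.5) == [((0,), 0.5), ((1,), 0.5)]

    def test_two_bins_independence(self):
        entries = generate_bin_frequencies([1, 1], 0.5)
        assert len(entries) == 4
        assert all(pr == pytest.approx(0.25) for _, pr in entries)

    def test_full_cartesian_product(self):
        entries = generate_bin_frequencies([2, 3], 0.7)
        assert len(entries) == 12
        assert sum(pr for _, pr in entries) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        bins=st.lists(st.integers(0, 6), min_size=1, max_size=4),
        p=st.floats(0, 1, allow_nan=False),
    )
    def test_normalization(self, bins, p):
        entries = generate_bin_frequencies(bins, p)
        assert sum(pr for _, pr in entries) == pytest.approx(1.0, abs=1e-12)


class TestProbBcs:
    def test_single_cluster_closed_form(self, params):
        # one window of 5, threshold ceil(0.8 * 5) = 4: binomial tail P(K >= 4)
        assert prob_bcs(BinVector((5,), 1), 0.5, params) == pytest.approx(0.1875)

    def test_empty_window_set(self, params):
        assert prob_bcs(BinVector((), 0), 0.5, params) == 0.0

    @staticmethod
    def bin_level_enumeration(bins, p, params):
        """Independent oracle: total probability of the union event over the
        full Cartesian product of per-bin biased counts."""
        n = bins.n_windows
        thresholds = [params.min_biased(bins.cluster_size(k)) for k in range(n)]
        total = 0.0
        for combo, pr in generate_bin_frequencies(bins.bin_sizes, p):
            if any(sum(combo[k : k + n]) >= thresholds[k] for k in range(n)):
                total += pr
        return total

    def test_two_cluster_case_vs_enumeration(self, params):
        bins = BinVector((2, 3, 2), 2)
        exact = prob_bcs(bins, 0.4, params)
        oracle = self.bin_level_enumeration(bins, 0.4, params)
        assert exact == pytest.approx(oracle, abs=1e-12)

    def test_random_bin_vectors_vs_enumeration(self, params):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(1, 4))
            sizes = rng.integers(0, 6, size=2 * n - 1)
            sizes[n - 1] = max(sizes[n - 1], 1)  # focal bin holds the focal sub
            bins = BinVector(tuple(int(s) for s in sizes), n)
            if min(bins.cluster_size(k) for k in range(n)) < params.min_cluster:
                continue
            p = float(rng.uniform(0, 1))
            assert prob_bcs(bins, p, params) == pytest.approx(
                self.bin_level_enumeration(bins, p, params), abs=1e-10
            )

    def test_position_level_oracle(self, params):
        pos = [0, 1, 150, 151, 152, 300, 301]
        wins = select_representative_windows(pos, 3, params)
        bins = compress_to_bins(wins, pos, 3, params)
        exact = prob_bcs(bins, 0.4, params)
        oracle = brute_force_prob_bcs(pos, 3, 0.4, params)
        assert exact == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_p(self, params):
        bins = BinVector((2, 3, 2), 2)
        assert prob_bcs(bins, 0.0, params) == 0.0
        assert prob_bcs(bins, 1.0, params) == 1.0

    def test_monotone_in_p(self, params):
        rng = np.random.default_rng(21)
        for _ in range(20):
            pos, f = random_instance(rng)
            wins = select_representative_windows(pos, f, params)
            if not wins:
                continue
            bins = compress_to_bins(wins, pos, f, params)
            values = [prob_bcs(bins, p, params) for p in np.linspace(0, 1, 11)]
            assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_monte_carlo_fallback_close_to_exact(self):
        exact_params = ClusterParams()
        mc_params = ClusterParams(max_exact_subs=4, mc_draws=200_000, mc_seed=7)
        pos = [0, 10, 40, 100, 180, 250, 290]
        wins = select_representative_windows(pos, 3, exact_params)
        bins = compress_to_bins(wins, pos, 3, exact_params)
        exact = prob_bcs(bins, 0.5, exact_params)
        approx = prob_bcs(bins, 0.5, mc_params)
        assert approx == pytest.approx(exact, abs=0.01)

    def test_cost_grows_with_covering_region(self, params):
        """Smoke check of the ~2^c scaling: a denser covering region takes
        longer but still completes within the exact cap."""
        import time

        rng = np.random.default_rng(3)
        small = np.sort(rng.choice(280, size=8, replace=False)).astype(np.int64)
        big = np.sort(rng.choice(280, size=20, replace=False)).astype(np.int64)
        for pos in (small, big):
            wins = select_representative_windows(pos, pos.size // 2, params)
            bins = compress_to_bins(wins, pos, pos.size // 2, params)
            t0 = time.perf_counter()
            val = prob_bcs(bins, 0.4, params)
            assert 0.0 <= val <= 1.0
            assert time.perf_counter() - t0 < 5.0


class TestObservedFlags:
    def test_six_subs_five_biased_all_flagged(self, params):
        cat = make_catalog([10, 50, 100, 150, 200, 250], [1, 1, 1, 1, 1, 0])
        assert observed_bcs_flags(cat, "1", params).sum() == 6

    def test_four_subs_none_flagged(self, params):
        cat = make_catalog([10, 80, 160, 240], [1, 1, 1, 1])
        assert observed_bcs_flags(cat, "1", params).sum() == 0

    def test_half_biased_none_flagged(self, params):
        cat = make_catalog([10, 50, 100, 150, 200, 250], [1, 1, 1, 0, 0, 0])
        assert observed_bcs_flags(cat, "1", params).sum() == 0

    @pytest.mark.parametrize("divisor", [1, 150])
    def test_matches_naive_scan(self, divisor):
        pr = ClusterParams(start_divisor=divisor)
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = int(rng.integers(2, 25))
            span = int(rng.integers(100, 1500))
            pos = np.sort(rng.choice(span, size=min(n, span), replace=False))
            lab = rng.random(pos.size) < 0.7
            cat = make_catalog(pos, lab, length=span + 400)
            flags = observed_bcs_flags(cat, "1", pr)
            naive = np.zeros(pos.size, dtype=bool)
            for s in range(0, span + 1):
                if s % divisor:
                    continue
                l = int(np.searchsorted(pos, s))
                r = int(np.searchsorted(pos, s + pr.window_size))
                if r - l >= pr.min_cluster and lab[l:r].sum() >= pr.min_biased(r - l):
                    naive[l:r] = True
            assert np.array_equal(flags, naive)


class TestRegions:
    def test_p_hat(self):
        cat = make_catalog(range(0, 100, 10), [1] * 7 + [0] * 3)
        assert estimate_p_hat(cat, "1", (0, 1000)) == pytest.approx(0.7)
        assert estimate_p_hat(cat, "1", (5000, 6000)) is None
        cat2 = make_catalog([5, 10], [1, 1])
        assert estimate_p_hat(cat2, "1", (0, 100)) == 1.0

    def test_region_without_clusters(self, params):
        cat = make_catalog([1000, 5000, 9000], [1, 0, 1], length=1_000_000)
        stat = ubcs_region(cat, "1", (0, 1_000_000), params)
        assert stat.observed == 0 and stat.expected == 0.0 and stat.ubcs == 0.0

    def test_region_composed_example(self, params):
        # a 5-substitution cluster, all biased, plus 5 isolated unbiased
        # substitutions: p_hat = 0.5, observed = 5, expected = 5 * 0.1875
        pos = [100, 150, 200, 250, 300] + [10_000, 20_000, 30_000, 40_000, 50_000]
        lab = [1] * 5 + [0] * 5
        cat = make_catalog(pos, lab, length=1_000_000)
        stat = ubcs_region(cat, "1", (0, 1_000_000), params)
        assert stat.p_hat == pytest.approx(0.5)
        assert stat.observed == 5
        assert stat.expected == pytest.approx(5 * 0.1875)
        assert stat.ubcs == pytest.approx(5 - 0.9375)

    def test_empty_region_marker(self, params):
        cat = make_catalog([100], [1], length=3_000_000)
        stat = ubcs_region(cat, "1", (2_000_000, 3_000_000), params)
        assert stat.p_hat is None and stat.n_subs == 0 and stat.ubcs == 0.0

    def test_profile_tiling(self, params):
        cat = make_catalog([100], [1], length=3_000_000)
        prof = ubcs_profile(cat, params)
        assert len(prof.regions["1"]) == 3
        assert not any(r.partial for r in prof.regions["1"])
        cat2 = make_catalog([100], [1], length=2_500_000)
        prof2 = ubcs_profile(cat2, params)
        regs = prof2.regions["1"]
        assert len(regs) == 3 and regs[-1].partial
        assert (regs[-1].start, regs[-1].end) == (2_000_000, 2_500_000)

    def test_profile_observed_totals(self, params):
        rng = np.random.default_rng(41)
        pos = np.sort(rng.choice(3_000_000, size=400, replace=False))
        lab = rng.random(400) < 0.6
        cat = make_catalog(pos, lab, length=3_000_000)
        prof = ubcs_profile(cat, params)
        total = sum(r.observed for r in prof.regions["1"])
        assert total == int(observed_bcs_flags(cat, "1", params).sum())
        assert sum(r.n_subs for r in prof.regions["1"]) == 400
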