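"""Observed and expected biased clustered substitutions (BCS) per region.

A substitution is *clustered* (CS) when some window of ``window_size`` bp
holds at least ``min_cluster`` substitutions including it, and *biased
clustered* (BCS) when such a window additionally has at least
``bias_threshold`` of its substitutions weak-to-strong.  The UBCS statistic
of a 1 Mb region is the observed BCS count minus its expectation under a
null in which bias labels are i.i.d. Bernoulli(p_hat), with p_hat the
region's weak-to-strong fraction.

The expectation is computed exactly.  For a focal substitution, every window
that may contain it is reduced to a minimal set of *representative* windows
(one witness per distinct contained substitution set, discarding windows
below ``min_cluster``).  The region they cover is compressed into ``2n - 1``
bins whose boundaries are the ordered window starts and ends; cluster ``k``
is the run of ``n`` consecutive bins starting at ``k`` and reproduces
representative window ``k``.  The union probability that any cluster is
biased is accumulated as a telescoping sum
``P(A_1) + P(A_2 & !A_1) + ...``, each term evaluated by conditioning on the
per-bin biased counts, whose conditional independence allows a dynamic
programme over the shared ``n - 1`` bins of consecutive clusters.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Sequence

import numpy as np

from .snd import SubstitutionCatalog

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterParams:
    """Window, cluster and region parameters of the BCS statistic.

    ``start_divisor`` restricts window starts to multiples of the divisor:
    1 enumerates every possible window (the exact mode), while 150 with a
    300 bp window reproduces the original half-overlapping scheme.
    ``max_exact_subs`` caps the substitution count of a covering region for
    the exact computation; denser neighbourhoods fall back to a seeded
    Monte-Carlo estimate of the union probability.
    """

    window_size: int = 300
    min_cluster: int = 5
    bias_threshold: float = 0.8
    start_divisor: int = 1
    region_size: int = 1_000_000
    max_exact_subs: int = 22
    mc_draws: int = 100_000
    mc_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not 0 < self.bias_threshold <= 1:
            raise ValueError("bias_threshold must be in (0, 1]")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be >= 1")
        if self.start_divisor < 1 or self.window_size % self.start_divisor:
            raise ValueError("start_divisor must divide window_size")
        if self.region_size <= 0:
            raise ValueError("region_size must be positive")

    def min_biased(self, cluster_size: int) -> int:
        """Smallest biased count meeting the threshold, by exact rational
        comparison (no floating-point boundary error at e.g. exactly 80%)."""
        num, den = _bias_fraction(self.bias_threshold)
        return _min_biased(cluster_size, num, den)


@lru_cache(maxsize=None)
def _bias_fraction(threshold: float) -> tuple[int, int]:
    frac = Fraction(str(threshold))
    return frac.numerator, frac.denominator


@lru_cache(maxsize=None)
def _min_biased(cluster_size: int, num: int, den: int) -> int:
    return -((-cluster_size * num) // den)


@dataclass(frozen=True)
class BinVector:
    """Compressed representation of the region covered by ``n`` representative
    windows: ``2n - 1`` substitution counts, the focal substitution sitting in
    the middle bin (index ``n - 1``)."""

    bin_sizes: tuple[int, ...]
    n_windows: int

    def __post_init__(self) -> None:
        if self.n_windows and len(self.bin_sizes) != 2 * self.n_windows - 1:
            raise ValueError("bin vector must have 2n - 1 bins")

    @property
    def focal_bin(self) -> int:
        return self.n_windows - 1

    @property
    def total(self) -> int:
        return int(sum(self.bin_sizes))

    def cluster_size(self, k: int) -> int:
        """Substitution count of cluster ``k`` (bins ``k .. k + n - 1``)."""
        return int(sum(self.bin_sizes[k : k + self.n_windows]))


@dataclass(frozen=True)
class RegionStat:
    """Observed/expected BCS bookkeeping for one region of the 1 Mb grid."""

    chromosome: str
    start: int
    end: int
    n_subs: int
    p_hat: float | None
    observed: int
    expected: float
    ubcs: float
    partial: bool = False


@dataclass
class UBCSProfile:
    """Ordered per-chromosome UBCS region statistics for one species pair and
    derivation direction."""

    direction: str
    regions: dict[str, list[RegionStat]]
    label: str = ""

    @property
    def chromosomes(self) -> list[str]:
        return list(self.regions)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "chromosome": r.chromosome,
                "region_start": r.start,
                "region_end": r.end,
                "n_subs": r.n_subs,
                "p_hat": float("nan") if r.p_hat is None else r.p_hat,
                "observed": r.observed,
                "expected": r.expected,
                "ubcs": r.ubcs,
                "partial": int(r.partial),
            }
            for regs in self.regions.values()
            for r in regs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chromosome",
                "region_start",
                "region_end",
                "n_subs",
                "p_hat",
                "observed",
                "expected",
                "ubcs",
                "partial",
            ],
        )


def _candidate_starts(
    positions: np.ndarray, focal_index: int, params: ClusterParams
) -> list[int]:
    """Window start coordinates at which the contained substitution set can
    change, restricted to divisor-aligned starts covering the focal position."""
    m, d = params.window_size, params.start_divisor
    f = int(positions[focal_index])
    lo = max(0, f - m + 1)
    hi = f
    if d > 1:
        first = -(-lo // d) * d
        return list(range(first, hi + 1, d))
    cand = {lo}
    il = int(np.searchsorted(positions, f - m + 1, side="left"))
    ir = int(np.searchsorted(positions, f + m, side="left"))
    for p in positions[il:ir]:
        p = int(p)
        for s in (p + 1, p - m + 1):
            if lo < s <= hi:
                cand.add(s)
    return sorted(cand)


def select_representative_windows(
    positions: Sequence[int] | np.ndarray,
    focal_index: int,
    params: ClusterParams,
) -> list[int]:
    """Start coordinates of the minimal witness set of windows around a focal
    substitution.

    Candidate windows are the divisor-aligned ``window_size`` windows that
    contain the focal position.  Windows with fewer than ``min_cluster``
    substitutions are dropped (they can never be biased clusters) and windows
    sharing the same substitution set are represented once, by the smallest
    start.  The number of representatives never exceeds the substitution
    count of the covered region.
    """
    pos = np.asarray(positions, dtype=np.int64)
    m = params.window_size
    starts = np.asarray(_candidate_starts(pos, focal_index, params), dtype=np.int64)
    if starts.size == 0:
        return []
    ls = np.searchsorted(pos, starts, side="left")
    rs = np.searchsorted(pos, starts + m, side="left")
    seen: set[tuple[int, int]] = set()
    out: list[int] = []
    for s, l, r in zip(starts.tolist(), ls.tolist(), rs.tolist()):
        if r - l < params.min_cluster or (l, r) in seen:
            continue
        seen.add((l, r))
        out.append(s)
    return out


def compress_to_bins(
    window_starts: Sequence[int],
    positions: Sequence[int] | np.ndarray,
    focal_index: int,
    params: ClusterParams,
) -> BinVector:
    """Compress the region covered by representative windows into 2n - 1 bins.

    Bin boundaries are the ordered starts and ends of all representative
    windows; the focal substitution must land in the middle bin and cluster
    ``k`` (bins ``k .. k + n - 1``) recovers the substitution count of the
    ``k``-th representative window.
    """
    starts = sorted(int(s) for s in window_starts)
    n = len(starts)
    if n == 0:
        raise ValueError("compress_to_bins requires at least one window")
    m = params.window_size
    pos = np.asarray(positions, dtype=np.int64)
    bounds = starts + [s + m for s in starts]
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("representative windows do not mutually overlap")
    idx = np.searchsorted(pos, bounds, side="left")
    sizes = tuple(int(idx[i + 1] - idx[i]) for i in range(2 * n - 1))
    if not idx[n - 1] <= focal_index < idx[n]:
        raise AssertionError("focal substitution not in the middle bin")
    return BinVector(bin_sizes=sizes, n_windows=n)


def binom_from(bin_size: int, start_size: int, p: float) -> float:
    """Upper binomial tail P(K >= start_size) for K ~ Binomial(bin_size, p)."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if start_size <= 0:
        return 1.0
    if start_size > bin_size:
        return 0.0
    q = 1.0 - p
    return float(
        sum(
            math.comb(bin_size, k) * p**k * q ** (bin_size - k)
            for k in range(start_size, bin_size + 1)
        )
    )


def _pmf_table(bin_size: int, p: float) -> list[float]:
    q = 1.0 - p
    return [
        math.comb(bin_size, x) * p**x * q ** (bin_size - x)
        for x in range(bin_size + 1)
    ]


def generate_bin_frequencies(
    bin_sizes: Sequence[int], p: float
) -> list[tuple[tuple[int, ...], float]]:
    """All joint biased-count vectors over the bins with their probabilities.

    One entry per vector ``x`` with ``0 <= x_i <= b_i`` (full Cartesian
    product); the probability is the product of independent binomial pmfs and
    the entries sum to one.
    """
    tables = [_pmf_table(b, p) for b in bin_sizes]
    out = []
    for combo in itertools.product(*(range(b + 1) for b in bin_sizes)):
        pr = 1.0
        for table, x in zip(tables, combo):
            pr *= table[x]
        out.append((combo, pr))
    return out


def _mc_union_probability(
    bins: BinVector,
    thresholds: Sequence[int],
    p: float,
    params: ClusterParams,
    rng: np.random.Generator | None,
) -> float:
    """Monte-Carlo estimate of the union probability for covering regions too
    dense for the exact dynamic programme."""
    if rng is None:
        rng = np.random.default_rng(params.mc_seed)
    n = bins.n_windows
    b = np.asarray(bins.bin_sizes)
    draws = rng.binomial(b, p, size=(params.mc_draws, b.size))
    csum = np.concatenate(
        [np.zeros((params.mc_draws, 1), dtype=np.int64), np.cumsum(draws, axis=1)],
        axis=1,
    )
    hit = np.zeros(params.mc_draws, dtype=bool)
    for k in range(n):
        hit |= (csum[:, k + n] - csum[:, k]) >= thresholds[k]
    return float(hit.mean())


def prob_bcs(
    bins: BinVector,
    p: float,
    params: ClusterParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Probability that the focal (middle-bin) substitution is BCS under the
    independent-labels null.

    Evaluates ``P(A_1 | ... | A_n)`` for clusters ``A_k`` over the bin vector,
    with bias labels i.i.d. Bernoulli(p), by the telescoping sum over
    ``P(A_k & !A_1 & ... & !A_{k-1})`` conditioned on the per-bin biased
    counts.  Covering regions with more than ``max_exact_subs`` substitutions
    are estimated by seeded Monte-Carlo instead.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    n = bins.n_windows
    if n == 0:
        return 0.0
    b = bins.bin_sizes
    thresholds = [params.min_biased(bins.cluster_size(k)) for k in range(n)]
    if bins.total > params.max_exact_subs:
        logger.warning(
            "covering region with %d substitutions exceeds exact cap %d; "
            "using Monte-Carlo with %d draws",
            bins.total,
            params.max_exact_subs,
            params.mc_draws,
        )
        return _mc_union_probability(bins, thresholds, p, params, rng)

    result = binom_from(bins.cluster_size(0), thresholds[0], p)
    if n == 1:
        return min(max(result, 0.0), 1.0)

    pmf = {bi: np.asarray(_pmf_table(bi, p)) for bi in set(b)}
    # tails[bi][j] = P(K >= j) for K ~ Binomial(bi, p), j = 0..bi+1
    tails = {
        bi: np.concatenate([np.cumsum(table[::-1])[::-1], [0.0]])
        for bi, table in pmf.items()
    }
    prev: np.ndarray | None = None  # P(no earlier cluster biased | shared bins)
    for k in range(1, n):
        cond = list(range(k, k + n - 1))  # the n - 1 bins shared with cluster k-1
        dims = [b[i] + 1 for i in cond]
        b_last = b[k + n - 1]
        b_prev = b[k - 1]
        pmf_prev = pmf[b_prev]
        # joint probability and index sum over the shared bins
        q = pmf[b[cond[0]]]
        for i in cond[1:]:
            q = np.multiply.outer(q, pmf[b[i]])
        s = np.arange(dims[0])
        for d in dims[1:]:
            s = np.add.outer(s, np.arange(d))
        p_biased = tails[b_last][np.clip(thresholds[k] - s, 0, b_last + 1)]
        # cutoff: the count of bin k-1 must stay below thresholds[k-1] - s
        cutoff = np.clip(thresholds[k - 1] - s, 0, b_prev + 1)
        if prev is None:
            cum = np.concatenate([[0.0], np.cumsum(pmf_prev)])
            p_not = cum[cutoff]
        else:
            w = prev * pmf_prev.reshape((-1,) + (1,) * (prev.ndim - 1))
            cum = np.concatenate(
                [np.zeros((1,) + w.shape[1:]), np.cumsum(w, axis=0)], axis=0
            )
            coords = np.ogrid[tuple(slice(0, d) for d in dims[:-1])]
            p_not = cum[tuple([cutoff] + [c[..., None] for c in coords])]
        result += float((q * p_biased * p_not).sum())
        prev = p_not
    return min(max(result, 0.0), 1.0)


def brute_force_prob_bcs(
    positions: Sequence[int] | np.ndarray,
    focal_index: int,
    p: float,
    params: ClusterParams,
    max_enumeration: int = 20,
) -> float:
    """Exact verification oracle: enumerate all bias labelings of the covering
    region and sum the probabilities of those in which some candidate window
    containing the focal substitution is a biased cluster.

    Independent of the compression/DP path; feasible only for small covering
    regions (``<= max_enumeration`` substitutions).
    """
    pos = np.asarray(positions, dtype=np.int64)
    m = params.window_size
    f = int(pos[focal_index])
    il = int(np.searchsorted(pos, f - m + 1, side="left"))
    ir = int(np.searchsorted(pos, f + m, side="left"))
    s = ir - il
    if s > max_enumeration:
        raise ValueError(f"covering region holds {s} > {max_enumeration} substitutions")
    windows: dict[tuple[int, int], int] = {}
    for start in _candidate_starts(pos, focal_index, params):
        l = int(np.searchsorted(pos, start, side="left"))
        r = int(np.searchsorted(pos, start + m, side="left"))
        if r - l < params.min_cluster:
            continue
        windows[(l - il, r - il)] = params.min_biased(r - l)
    if not windows:
        return 0.0
    codes = np.arange(2**s)
    bits = (codes[:, None] >> np.arange(s)) & 1
    csum = np.concatenate(
        [np.zeros((codes.size, 1), dtype=np.int64), np.cumsum(bits, axis=1)], axis=1
    )
    hit = np.zeros(codes.size, dtype=bool)
    for (l, r), t in windows.items():
        hit |= (csum[:, r] - csum[:, l]) >= t
    k = bits.sum(axis=1)
    weights = p**k * (1.0 - p) ** (s - k)
    return float(weights[hit].sum())


def observed_bcs_flags(
    catalog: SubstitutionCatalog,
    chromosome: str,
    params: ClusterParams,
    neighbor_counts: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean flag per substitution: lies in some qualifying window (at least
    ``min_cluster`` substitutions, at least ``bias_threshold`` weak-to-strong).
    The flagged substitution itself need not be biased.
    """
    pos = catalog.positions[chromosome]
    lab = catalog.biased[chromosome].astype(np.int64)
    n = pos.size
    flags = np.zeros(n, dtype=bool)
    if n == 0:
        return flags
    m, d, mc = params.window_size, params.start_divisor, params.min_cluster
    cum = np.concatenate([[0], np.cumsum(lab)])
    if neighbor_counts is None:
        neighbor_counts = np.searchsorted(pos, pos + m, side="left") - np.searchsorted(
            pos, pos - m + 1, side="left"
        )
    if d == 1:
        pl = pos.tolist()
        cl = cum.tolist()
        # only substitutions with enough neighbours can start a qualifying run
        for i in np.nonzero(neighbor_counts >= mc)[0].tolist():
            s_min_i = 0 if i == 0 else pl[i - 1] + 1
            s_max_i = pl[i]
            j = i + mc
            while j <= n and pl[j - 1] - pl[i] <= m - 1:
                lo = max(s_min_i, pl[j - 1] - m + 1, 0)
                hi = s_max_i if j == n else min(s_max_i, pl[j] - m)
                if lo <= hi and cl[j] - cl[i] >= params.min_biased(j - i):
                    flags[i:j] = True
                j += 1
    else:
        starts: set[int] = set()
        for p_ in pos[neighbor_counts >= mc]:
            p_ = int(p_)
            lo = max(0, p_ - m + 1)
            first = -(-lo // d) * d
            starts.update(range(first, p_ + 1, d))
        for s in starts:
            l = int(np.searchsorted(pos, s, side="left"))
            r = int(np.searchsorted(pos, s + m, side="left"))
            if r - l >= mc and cum[r] - cum[l] >= params.min_biased(r - l):
                flags[l:r] = True
    return flags


def estimate_p_hat(
    catalog: SubstitutionCatalog,
    chromosome: str,
    region: tuple[int, int],
) -> float | None:
    """Weak-to-strong fraction among the substitutions of a region; ``None``
    when the region holds no substitutions."""
    pos = catalog.positions[chromosome]
    lab = catalog.biased[chromosome]
    l = int(np.searchsorted(pos, region[0], side="left"))
    r = int(np.searchsorted(pos, region[1], side="left"))
    if r == l:
        return None
    return float(lab[l:r].sum() / (r - l))


def ubcs_region(
    catalog: SubstitutionCatalog,
    chromosome: str,
    region: tuple[int, int],
    params: ClusterParams,
    flags: np.ndarray | None = None,
    neighbor_counts: np.ndarray | None = None,
    partial: bool = False,
    rng: np.random.Generator | None = None,
) -> RegionStat:
    """Observed, expected and UBCS for one region of the 1 Mb grid.

    p_hat comes from the region containing each focal substitution, while
    windows and clusters are built chromosome-wide (they may straddle the
    region boundary).  A region with no substitutions is emitted with zero
    counts and an undefined p_hat.
    """
    pos = catalog.positions[chromosome]
    l = int(np.searchsorted(pos, region[0], side="left"))
    r = int(np.searchsorted(pos, region[1], side="left"))
    n_subs = r - l
    p_hat = estimate_p_hat(catalog, chromosome, region)
    if p_hat is None:
        return RegionStat(chromosome, region[0], region[1], 0, None, 0, 0.0, 0.0, partial)
    m = params.window_size
    if neighbor_counts is None:
        neighbor_counts = np.searchsorted(pos, pos + m, side="left") - np.searchsorted(
            pos, pos - m + 1, side="left"
        )
    if flags is None:
        flags = observed_bcs_flags(catalog, chromosome, params, neighbor_counts)
    observed = int(flags[l:r].sum())
    expected = 0.0
    candidates = l + np.nonzero(neighbor_counts[l:r] >= params.min_cluster)[0]
    for i in candidates.tolist():
        wins = select_representative_windows(pos, i, params)
        if not wins:
            continue
        bins = compress_to_bins(wins, pos, i, params)
        expected += prob_bcs(bins, p_hat, params, rng=rng)
    return RegionStat(
        chromosome,
        region[0],
        region[1],
        n_subs,
        p_hat,
        observed,
        expected,
        observed - expected,
        partial,
    )


def ubcs_profile(
    catalog: SubstitutionCatalog,
    params: ClusterParams,
    label: str = "",
) -> UBCSProfile:
    """UBCS RegionStats over the consecutive 1 Mb tiling of every chromosome.

    The final region of a chromosome whose length is not a multiple of the
    region size is emitted with ``partial=True``.
    """
    regions: dict[str, list[RegionStat]] = {}
    size = params.region_size
    for chrom, length in catalog.chromosome_lengths.items():
        pos = catalog.positions.get(chrom, np.empty(0, dtype=np.int64))
        if chrom in catalog.positions:
            m = params.window_size
            counts = np.searchsorted(pos, pos + m, side="left") - np.searchsorted(
                pos, pos - m + 1, side="left"
            )
            flags = observed_bcs_flags(catalog, chrom, params, counts)
        else:
            flags = np.empty(0, dtype=bool)
            counts = np.empty(0, dtype=np.int64)
        stats = []
        n_tiles = -(-length // size)
        for t in range(n_tiles):
            start = t * size
            end = min((t + 1) * size, length)
            partial = end - start < size
            if chrom in catalog.positions:
                stat = ubcs_region(
                    catalog,
                    chrom,
                    (start, end),
                    params,
                    flags=flags,
                    neighbor_counts=counts,
                    partial=partial,
                )
            else:
                stat = RegionStat(chrom, start, end, 0, None, 0, 0.0, 0.0, partial)
            stats.append(stat)
        regions[chrom] = stats
    return UBCSProfile(direction=catalog.direction.value, regions=regions, label=label)
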