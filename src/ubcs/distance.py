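"""Evolutionary distances from telomeric UBCS proportions.

Telomeric UBCS accumulates approximately linearly with divergence time, so
the ratio of summed telomeric UBCS between two species pairs estimates the
ratio of their divergence times.  Per chromosome arm the ratio T is the sum
of the UBCS values of the first (p arm) or last (q arm) M 1-Mb windows of
one profile over the same windows of the other; the distance is the median
of T over a fixed set of control telomeres unaffected by large-scale
rearrangements.  Confidence intervals come from a bootstrap that resamples
telomeres and window offsets; multiplying the proportion by a fixed
human-chimpanzee split time converts it into a speciation time in Mya.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import UBCSProfile

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(i) for i in range(1, 23))


def _norm_chrom(chrom: str | int) -> str:
    chrom = str(chrom)
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class ControlSets:
    """Control chromosomes whose p / q arm telomeres enter the median."""

    ct_p: frozenset[str] = frozenset(
        {"1", "4", "5", "6", "8", "10", "12", "16", "17", "19"}
    )
    ct_q: frozenset[str] = frozenset(
        set(AUTOSOMES) - {"15", "18", "19", "20"}
    )

    def __post_init__(self) -> None:
        if not self.ct_p or not self.ct_q:
            raise ValueError("control sets must be nonempty")
        for s in (self.ct_p, self.ct_q):
            unknown = {c for c in s if c not in AUTOSOMES}
            if unknown:
                raise ValueError(f"not autosomes: {sorted(unknown)}")

    @property
    def telomeres(self) -> list[tuple[str, str]]:
        """(chromosome, arm) pairs in a stable order."""
        key = lambda c: int(c)
        return [(c, "p") for c in sorted(self.ct_p, key=key)] + [
            (c, "q") for c in sorted(self.ct_q, key=key)
        ]

    @property
    def n_telomeres(self) -> int:
        return len(self.ct_p) + len(self.ct_q)


@dataclass(frozen=True)
class DistanceParams:
    """Telomere-window and bootstrap settings of the proportion estimator."""

    windows_per_arm: int = 10
    n_boot: int = 1000
    telomere_draw: int = 15
    window_draw: int = 8
    trim_fraction: float = 0.05
    split_time_mya: float = 6.0
    per_telomere_windows: bool = False

    def __post_init__(self) -> None:
        if self.window_draw > self.windows_per_arm:
            raise ValueError("window_draw must not exceed windows_per_arm")
        if not 0 <= self.trim_fraction < 1:
            raise ValueError("trim_fraction must be in [0, 1)")


@dataclass
class ProportionEstimate:
    """Median telomeric UBCS proportion with its bootstrap CI and the derived
    speciation time."""

    proportion: float
    ratios: dict[tuple[str, str], float]
    excluded: list[tuple[str, str]] = field(default_factory=list)
    ci: tuple[float, float] | None = None
    time_mya: float | None = None
    time_ci: tuple[float, float] | None = None


def _arm_values(profile: UBCSProfile, chromosome: str, arm: str, m: int) -> np.ndarray:
    """UBCS values of the M telomeric windows of one arm, ordered from the
    chromosome end inward (q-arm windows are taken in reversed order)."""
    lookup = {_norm_chrom(c): c for c in profile.regions}
    chrom = _norm_chrom(chromosome)
    if chrom not in lookup:
        raise KeyError(f"chromosome {chromosome} missing from profile")
    regs = [r for r in profile.regions[lookup[chrom]] if not r.partial]
    if arm == "p":
        chosen = regs[:m]
    elif arm == "q":
        chosen = regs[::-1][:m]
    else:
        raise ValueError("arm must be 'p' or 'q'")
    if len(chosen) < m:
        logger.warning(
            "chromosome %s %s arm has only %d full windows (%d requested)",
            chromosome,
            arm,
            len(chosen),
            m,
        )
    return np.array([r.ubcs for r in chosen], dtype=float)


def arm_proportion(
    profile_x: UBCSProfile,
    profile_y: UBCSProfile,
    chromosome: str,
    arm: str,
    m: int = 10,
) -> float | None:
    """Ratio of summed telomeric UBCS of profile_x over profile_y for one arm;
    ``None`` when the denominator sum is not positive."""
    ux = _arm_values(profile_x, chromosome, arm, m)
    uy = _arm_values(profile_y, chromosome, arm, m)
    den = float(uy.sum())
    if den <= 0:
        logger.warning(
            "telomere %s%s excluded: non-positive denominator UBCS sum %.3g",
            chromosome,
            arm,
            den,
        )
        return None
    return float(ux.sum() / den)


def ubcs_distance(
    profile_x: UBCSProfile,
    profile_y: UBCSProfile,
    control: ControlSets | None = None,
    params: DistanceParams | None = None,
) -> ProportionEstimate:
    """Median UBCS proportion of profile_x relative to profile_y over the
    control telomeres (point estimate only)."""
    control = control or ControlSets()
    params = params or DistanceParams()
    ratios: dict[tuple[str, str], float] = {}
    excluded: list[tuple[str, str]] = []
    for chrom, arm in control.telomeres:
        t = arm_proportion(profile_x, profile_y, chrom, arm, params.windows_per_arm)
        if t is None:
            excluded.append((chrom, arm))
        else:
            ratios[(chrom, arm)] = t
    if not ratios:
        raise ValueError("all telomere ratios undefined")
    return ProportionEstimate(
        proportion=float(np.median(list(ratios.values()))),
        ratios=ratios,
        excluded=excluded,
    )


def bootstrap_distance(
    profile_x: UBCSProfile,
    profile_y: UBCSProfile,
    control: ControlSets | None = None,
    params: DistanceParams | None = None,
    seed: int | None = None,
) -> tuple[float, float]:
    """Bootstrap CI of the UBCS proportion.

    Each replicate draws ``telomere_draw`` telomeres with replacement from the
    control pool and ``window_draw`` of the M window offsets with replacement
    (shared across the sampled telomeres unless ``per_telomere_windows``),
    recomputes the median proportion, and the CI is the value range left after
    trimming ``trim_fraction / 2`` of the replicates from each tail.
    """
    control = control or ControlSets()
    params = params or DistanceParams()
    m = params.windows_per_arm
    pool = control.telomeres
    ux = np.full((len(pool), m), np.nan)
    uy = np.full((len(pool), m), np.nan)
    for i, (chrom, arm) in enumerate(pool):
        vx = _arm_values(profile_x, chrom, arm, m)
        vy = _arm_values(profile_y, chrom, arm, m)
        ux[i, : vx.size] = vx
        uy[i, : vy.size] = vy
    k_draw = params.telomere_draw
    if k_draw > len(pool):
        logger.warning(
            "telomere_draw %d exceeds pool of %d; drawing from the full pool",
            k_draw,
            len(pool),
        )
        k_draw = len(pool)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(params.n_boot):
        tel = rng.integers(0, len(pool), size=k_draw)
        if params.per_telomere_windows:
            win = rng.integers(0, m, size=(k_draw, params.window_draw))
            num = np.take_along_axis(ux[tel], win, axis=1).sum(axis=1)
            den = np.take_along_axis(uy[tel], win, axis=1).sum(axis=1)
        else:
            win = rng.integers(0, m, size=params.window_draw)
            num = ux[np.ix_(tel, win)].sum(axis=1)
            den = uy[np.ix_(tel, win)].sum(axis=1)
        valid = np.isfinite(den) & np.isfinite(num) & (den > 0)
        if not valid.any():
            continue
        reps.append(float(np.median(num[valid] / den[valid])))
    if not reps:
        raise ValueError("no valid bootstrap replicates")
    reps = np.sort(np.asarray(reps))
    k = int(np.floor(reps.size * params.trim_fraction / 2))
    return float(reps[k]), float(reps[reps.size - 1 - k])


def speciation_time(
    estimate: ProportionEstimate, split_time_mya: float = 6.0
) -> ProportionEstimate:
    """Scale a UBCS proportion (and its CI) by the reference split time to
    obtain a speciation time in Mya."""
    time = estimate.proportion * split_time_mya
    time_ci = None
    if estimate.ci is not None:
        time_ci = (estimate.ci[0] * split_time_mya, estimate.ci[1] * split_time_mya)
    return replace(estimate, time_mya=time, time_ci=time_ci)


def estimate_distance(
    profile_x: UBCSProfile,
    profile_y: UBCSProfile,
    control: ControlSets | None = None,
    params: DistanceParams | None = None,
    seed: int | None = None,
) -> ProportionEstimate:
    """Point estimate, bootstrap CI and derived speciation time in one call."""
    params = params or DistanceParams()
    est = ubcs_distance(profile_x, profile_y, control, params)
    est.ci = bootstrap_distance(profile_x, profile_y, control, params, seed=seed)
    return speciation_time(est, params.split_time_mya)
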