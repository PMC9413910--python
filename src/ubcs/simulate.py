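"""Synthetic substitution catalogs and alignment fixtures.

The generator emulates the statistical structure the UBCS method relies on:
point substitutions along a chromosome, a Neyman-Scott cluster process
(Poisson cluster centres, Poisson offspring scattered over a short span)
whose rate is elevated near chromosome ends with an exponential decay, a
weak-to-strong bias fraction raised inside clusters relative to the
background, and substitution counts that scale linearly with divergence
time.  Chromosomes are scaled down relative to real genomes (tens of Mb) so
that every stage of the pipeline is testable in seconds.

Cluster members keep a minimum spacing of ``min_spacing`` bp, mirroring the
density filter of the SND caller (which discards substitutions with more
than one other difference inside their 11-bp context window); this is also
what makes alignment fixtures round-trip exactly through the caller.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .fusion import FusionParams
from .snd import Derivation, SubstitutionCatalog

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


def default_autosomes(length: int = 20_000_000) -> dict[str, int]:
    """The 22 autosomes at a scaled-down common length."""
    return {str(i): length for i in range(1, 23)}


@dataclass(frozen=True)
class SimulationParams:
    """Rates and geometry of the synthetic substitution process.

    All rates are per bp per unit of ``time_scale`` (1.0 = the reference
    human-chimpanzee divergence).  ``telomere_cluster_rate`` is the extra
    cluster-centre intensity at a chromosome end, decaying exponentially
    inward with scale ``telomere_decay``.
    """

    chromosome_lengths: Mapping[str, int] = field(default_factory=default_autosomes)
    background_rate: float = 5e-4
    interior_cluster_rate: float = 2e-7
    telomere_cluster_rate: float = 6e-6
    telomere_decay: float = 2e6
    cluster_mean_size: float = 7.0
    cluster_span: int = 300
    min_spacing: int = 6
    p0: float = 0.25
    p1: float = 0.9
    time_scale: float = 1.0
    direction: Derivation = Derivation.TARGET

    def __post_init__(self) -> None:
        if not 0 <= self.p0 < self.p1 <= 1:
            raise ValueError("need 0 <= p0 < p1 <= 1")
        if self.time_scale <= 0:
            raise ValueError("time_scale must be positive")
        if self.cluster_span < self.min_spacing:
            raise ValueError("cluster_span must exceed min_spacing")


def _truncated_exponential(
    rng: np.random.Generator, scale: float, upper: float, size: int
) -> np.ndarray:
    u = rng.random(size)
    return -scale * np.log1p(-u * (1.0 - math.exp(-upper / scale)))


def _cluster_members(
    rng: np.random.Generator, centers: np.ndarray, sizes: np.ndarray, params: SimulationParams
) -> np.ndarray:
    """Scatter cluster members on a ``min_spacing`` lattice within the span;
    positions falling off the chromosome are reflected back by the caller."""
    span, gap = params.cluster_span, params.min_spacing
    slots = span // gap
    out = []
    for c, k in zip(centers, sizes):
        k = min(int(k), slots)
        offs = rng.choice(slots, size=k, replace=False) * gap - span // 2
        out.append(int(c) + offs)
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(out).astype(np.int64)


def _simulate_chromosome(
    rng: np.random.Generator,
    length: int,
    params: SimulationParams,
    extra_sources: Sequence[tuple[float, float, int, int, float]] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and bias labels for one chromosome.

    ``extra_sources`` are additional exponential cluster-centre components as
    (rate_per_bp_at_origin, decay_bp, origin, direction(+1/-1), shift_bp);
    the shift attenuates the component as if its origin lay ``shift`` bp
    beyond the accessible sequence.
    """
    t = params.time_scale
    centers = []
    # interior clusters, homogeneous
    n_int = rng.poisson(params.interior_cluster_rate * t * length)
    centers.append(rng.random(n_int) * length)
    # telomeric clusters, truncated-exponential from both ends
    lam = params.telomere_decay
    mean_tel = params.telomere_cluster_rate * t * lam * (1.0 - math.exp(-length / lam))
    for left in (True, False):
        n = rng.poisson(mean_tel)
        x = _truncated_exponential(rng, lam, length, n)
        centers.append(x if left else length - 1 - x)
    for rate, decay, origin, sign, shift in extra_sources:
        upper = length - origin if sign > 0 else origin
        mean = (
            rate
            * t
            * decay
            * math.exp(-shift / decay)
            * (1.0 - math.exp(-upper / decay))
        )
        n = rng.poisson(mean)
        x = _truncated_exponential(rng, decay, upper, n)
        centers.append(origin + sign * x)
    centers = np.concatenate(centers)
    sizes = 1 + rng.poisson(max(params.cluster_mean_size - 1.0, 0.0), centers.size)
    cpos = _cluster_members(rng, centers, sizes, params)
    clab = rng.random(cpos.size) < params.p1
    n_bg = rng.poisson(params.background_rate * t * length)
    bpos = rng.integers(0, length, size=n_bg)
    blab = rng.random(n_bg) < params.p0
    pos = np.concatenate([cpos, bpos])
    lab = np.concatenate([clab, blab])
    # reflect positions that fell off the chromosome
    pos = np.where(pos < 0, -pos - 1, pos)
    pos = np.where(pos >= length, 2 * length - 1 - pos, pos)
    pos = np.clip(pos, 0, length - 1)
    order = np.argsort(pos, kind="stable")
    pos, lab = pos[order], lab[order]
    # enforce the minimum spacing greedily (drop the later of close pairs)
    keep = np.ones(pos.size, dtype=bool)
    last = -params.min_spacing
    for i in range(pos.size):
        if pos[i] - last < params.min_spacing:
            keep[i] = False
        else:
            last = pos[i]
    return pos[keep], lab[keep]


def simulate_catalog(
    params: SimulationParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SubstitutionCatalog:
    """A substitution catalog drawn from the clustered, telomere-enriched,
    bias-elevated process.  Identical seeds yield identical catalogs."""
    params = params or SimulationParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    positions, biased = {}, {}
    for chrom, length in params.chromosome_lengths.items():
        pos, lab = _simulate_chromosome(rng, int(length), params)
        positions[chrom] = pos
        biased[chrom] = lab
    return SubstitutionCatalog(
        direction=params.direction,
        chromosome_lengths=dict(params.chromosome_lengths),
        positions=positions,
        biased=biased,
    )


def simulate_species_pair(
    t_x: float,
    t_y: float,
    params: SimulationParams | None = None,
    seed: int | None = None,
) -> tuple[SubstitutionCatalog, SubstitutionCatalog]:
    """Two independent catalogs whose substitution and cluster intensities
    scale linearly with the divergence times ``t_x`` and ``t_y``."""
    if t_x <= 0 or t_y <= 0:
        raise ValueError("divergence times must be positive")
    params = params or SimulationParams()
    ss = np.random.SeedSequence(seed)
    rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(2))
    cat_x = simulate_catalog(
        replace(params, time_scale=params.time_scale * t_x), rng=rng_x
    )
    cat_y = simulate_catalog(
        replace(params, time_scale=params.time_scale * t_y), rng=rng_y
    )
    return cat_x, cat_y


@dataclass
class FusionScenario:
    """Catalogs of a synthetic fusion experiment plus the matching estimator
    geometry."""

    catalog_human: SubstitutionCatalog
    catalog_query: SubstitutionCatalog
    fusion_params: FusionParams
    r_true: float


def fusion_scenario_params(chromosome_length: int = 20_000_000) -> SimulationParams:
    """Scaled geometry of the fusion experiment: the 14 control chromosomes
    (which include chromosome 2, whose real telomeres are intact)."""
    chroms = {str(i): chromosome_length for i in list(range(1, 13)) + [16, 17]}
    return SimulationParams(
        chromosome_lengths=chroms,
        background_rate=1e-3,
        telomere_cluster_rate=9e-6,
        telomere_decay=2e6,
        interior_cluster_rate=0.0,
    )


def simulate_fusion_scenario(
    split_time: float = 6.0,
    fusion_time: float = 1.0,
    params: SimulationParams | None = None,
    seed: int | None = None,
    fusion_site: int | None = None,
    interval_offset: int = 1_000_000,
    region_sizes: tuple[int, ...] = (3_000_000, 4_000_000, 5_000_000),
    site_rate_factor: float = 4.0,
) -> FusionScenario:
    """Catalog pair embodying a chromosome fusion ``fusion_time`` Mya ago.

    Control chromosomes accumulate telomeric clusters for the full split
    period in both derivation directions.  At the internal fusion site the
    human-derived signal accumulates a telomere-shaped component only for the
    pre-fusion fraction R = (split - fusion) / split of the period, while the
    query-derived component accumulates for the full period but with its
    origin shifted ``interval_offset`` bp outward — emulating the query
    telomere caps that are missing from the reference coordinates and that
    the rescaling factor q2 corrects for.
    """
    if not 0 <= fusion_time <= split_time:
        raise ValueError("need 0 <= fusion_time <= split_time")
    params = params or fusion_scenario_params()
    if "2" not in params.chromosome_lengths:
        raise ValueError("fusion scenario requires chromosome 2")
    site = fusion_site
    if site is None:
        site = int(params.chromosome_lengths["2"]) // 2
    r_true = (split_time - fusion_time) / split_time
    ss = np.random.SeedSequence(seed)
    rngs = dict(zip(("human", "query"), (np.random.default_rng(s) for s in ss.spawn(2))))
    site_rate = site_rate_factor * params.telomere_cluster_rate
    decay = params.telomere_decay
    sources = {
        "human": [
            (site_rate * r_true, decay, site, +1, 0.0),
            (site_rate * r_true, decay, site, -1, 0.0),
        ],
        "query": [
            (site_rate, decay, site, +1, float(interval_offset)),
            (site_rate, decay, site, -1, float(interval_offset)),
        ],
    }
    catalogs = {}
    for which, rng in rngs.items():
        positions, biased = {}, {}
        for chrom, length in params.chromosome_lengths.items():
            extra = sources[which] if chrom == "2" else ()
            pos, lab = _simulate_chromosome(rng, int(length), params, extra)
            positions[chrom] = pos
            biased[chrom] = lab
        catalogs[which] = SubstitutionCatalog(
            direction=Derivation.TARGET if which == "human" else Derivation.QUERY,
            chromosome_lengths=dict(params.chromosome_lengths),
            positions=positions,
            biased=biased,
        )
    fparams = FusionParams(
        fusion_site=site,
        interval_offset=interval_offset,
        region_sizes=region_sizes,
        split_time_mya=split_time,
    )
    return FusionScenario(
        catalog_human=catalogs["human"],
        catalog_query=catalogs["query"],
        fusion_params=fparams,
        r_true=r_true,
    )


# --------------------------------------------------------------------------
# alignment fixtures


@dataclass
class FixtureInfo:
    """Bookkeeping of an emitted alignment fixture."""

    n_columns: int
    n_decoys: dict[str, int]


def _sub_bases(
    rng: np.random.Generator, biased: bool, direction: Derivation
) -> tuple[str, str, str]:
    """(target, query, outgroup) bases realizing one substitution."""
    if biased:
        anc = rng.choice(["A", "T"])
        der = rng.choice(["C", "G"])
    else:
        anc = rng.choice(["C", "G"])  # strong ancestral state is never biased
        der = rng.choice([b for b in "ACGT" if b != anc])
    if direction is Derivation.TARGET:
        return der, anc, anc
    return anc, der, anc


def make_alignment_fixture(
    catalog: SubstitutionCatalog,
    tsv_path: str | Path,
    maf_path: str | Path | None = None,
    seed: int = 0,
    decoys: bool = True,
    context_half_width: int = 5,
) -> FixtureInfo:
    """Write a three-way TSV (and optionally a MAF) whose SND calling and
    polarization reproduce the input catalog exactly.

    Context columns are identical in target and query; each catalog entry
    becomes one clean SND column.  When ``decoys`` is on, blocks violating
    each filter are injected into gaps between real substitutions: a window
    with a query gap, a window with three target/query differences, and a
    clean SND without an outgroup base.  All decoys must be discarded by the
    caller, so the round-trip identity is unaffected.
    """
    rng = np.random.default_rng(seed)
    w = context_half_width
    n_decoys = {"gap": 0, "dense": 0, "outgroup": 0}
    rows: list[tuple[str, int, str, str, str]] = []
    n_columns = 0

    def chrom_key(c: str) -> tuple[int, str]:
        return (0, f"{int(c):05d}") if c.isdigit() else (1, c)

    for chrom in sorted(catalog.positions, key=chrom_key):
        pos = catalog.positions[chrom]
        lab = catalog.biased[chrom]
        length = catalog.chromosome_lengths[chrom]
        subs = {int(p): bool(b) for p, b in zip(pos, lab)}
        # merge the 11-bp windows into segments of needed columns
        segments: list[list[int]] = []
        for p in pos:
            a, b = max(0, int(p) - w), min(length, int(p) + w + 1)
            if segments and a <= segments[-1][1]:
                segments[-1][1] = max(segments[-1][1], b)
            else:
                segments.append([a, b])
        decoy_cols: dict[int, tuple[str, str, str]] = {}
        if decoys:
            gaps = []
            prev_end = 0
            for a, b in segments:
                if a - prev_end >= 4 * (2 * w + 1):
                    gaps.append((prev_end, a))
                prev_end = b
            if length - prev_end >= 4 * (2 * w + 1):
                gaps.append((prev_end, length))
            kinds = ["gap", "dense", "outgroup"]
            ki = 0
            for ga, gb in gaps[:6]:
                c = (ga + gb) // 2
                kind = kinds[ki % 3]
                ki += 1
                n_decoys[kind] += 1
                block = {}
                for q in range(c - w, c + w + 1):
                    base = str(rng.choice(_BASES))
                    block[q] = (base, base, base)
                tb, qb, ob = _sub_bases(rng, True, catalog.direction)
                if kind == "gap":
                    block[c] = (tb, qb, ob)
                    gb_base = str(rng.choice(_BASES))
                    block[c + 2] = (gb_base, "-", gb_base)
                elif kind == "dense":
                    for q in (c - 2, c, c + 2):
                        tb, qb, ob = _sub_bases(rng, True, catalog.direction)
                        block[q] = (tb, qb, ob)
                else:  # missing outgroup
                    block[c] = (tb, qb, ".")
                decoy_cols.update(block)
        all_cols: dict[int, tuple[str, str, str]] = dict(decoy_cols)
        for a, b in segments:
            for q in range(a, b):
                if q in subs:
                    all_cols[q] = _sub_bases(rng, subs[q], catalog.direction)
                else:
                    base = str(rng.choice(_BASES))
                    all_cols[q] = (base, base, base)
        for q in sorted(all_cols):
            tb, qb, ob = all_cols[q]
            rows.append((chrom, q, tb, qb, ob))
        n_columns += len(all_cols)

    tsv_path = Path(tsv_path)
    with tsv_path.open("w") as fh:
        fh.write("chromosome\tposition\ttarget_base\tquery_base\toutgroup_base\n")
        for chrom, q, tb, qb, ob in rows:
            fh.write(f"{chrom}\t{q}\t{tb}\t{qb}\t{ob}\n")

    if maf_path is not None:
        _write_maf(rows, catalog.chromosome_lengths, Path(maf_path))
    return FixtureInfo(n_columns=n_columns, n_decoys=n_decoys)


def _write_maf(
    rows: Sequence[tuple[str, int, str, str, str]],
    chromosome_lengths: Mapping[str, int],
    path: Path,
) -> None:
    """Emit the target/query columns as MAF blocks (one per contiguous run)."""
    with path.open("w") as fh:
        fh.write("##maf version=1\n")
        block: list[tuple[int, str, str]] = []

        def flush(chrom: str) -> None:
            if not block:
                return
            start = block[0][0]
            tseq = "".join(b[1] for b in block)
            qseq = "".join(b[2] for b in block)
            src = chromosome_lengths[chrom]
            qsize = sum(1 for ch in qseq if ch != "-")
            fh.write("a score=0.0\n")
            fh.write(f"s target.{chrom} {start} {len(tseq)} + {src} {tseq}\n")
            fh.write(f"s query.{chrom} {start} {qsize} + {src} {qseq}\n\n")
            block.clear()

        last_chrom = None
        last_pos = None
        for chrom, q, tb, qb, _ in rows:
            if chrom != last_chrom or (last_pos is not None and q != last_pos + 1):
                if last_chrom is not None:
                    flush(last_chrom)
            block.append((q, tb, qb))
            last_chrom, last_pos = chrom, q
        if last_chrom is not None:
            flush(last_chrom)
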