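"""Calling, filtering and polarizing single-nucleotide differences (SNDs).

An SND is a position where the target genome (e.g. human) and an aligned
query genome (e.g. chimpanzee) carry different bases.  Each candidate SND is
screened in an 11-bp context window centred on it and then polarized against
an outgroup base (e.g. Rhesus): if the target matches the outgroup the change
happened on the query lineage, and vice versa.  A conclusive substitution is
*biased* (weak-to-strong) when the ancestral outgroup base is A or T and the
derived base is C or G — the signature of GC-biased gene conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ACGT = frozenset("ACGT")
GAP = "-"
WEAK = frozenset("AT")
STRONG = frozenset("CG")


class Derivation(str, Enum):
    """Lineage assignment of a polarized substitution."""

    TARGET = "derived_in_target"
    QUERY = "derived_in_query"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class AlignedColumn:
    """One column of a pairwise alignment in target coordinates.

    ``position`` is the 0-based coordinate of the target base.  For columns
    where the target carries a gap (an insertion in the query) the position of
    the next target base is reported.  ``outgroup_base`` is ``None`` when the
    column could not be lifted over to the outgroup genome.
    """

    chromosome: str
    position: int
    target_base: str
    query_base: str
    outgroup_base: str | None = None

    def normalized(self) -> "AlignedColumn":
        og = self.outgroup_base.upper() if self.outgroup_base else None
        return replace(
            self,
            target_base=self.target_base.upper(),
            query_base=self.query_base.upper(),
            outgroup_base=og,
        )


@dataclass
class SubstitutionRecord:
    """A single target/query difference with its filter and polarity state."""

    chromosome: str
    position: int
    target_base: str
    query_base: str
    outgroup_base: str | None
    passed_filters: bool
    derivation: Derivation | None = None
    biased: bool = False

    @property
    def derived_base(self) -> str | None:
        if self.derivation is Derivation.TARGET:
            return self.target_base
        if self.derivation is Derivation.QUERY:
            return self.query_base
        return None

    @property
    def ancestral_base(self) -> str | None:
        if self.derivation is Derivation.TARGET:
            return self.query_base
        if self.derivation is Derivation.QUERY:
            return self.target_base
        return None


@dataclass
class SubstitutionCatalog:
    """Direction-specific, per-chromosome sorted substitution positions.

    ``positions[chrom]`` is a strictly increasing int64 array, and
    ``biased[chrom]`` the parallel boolean weak-to-strong labels.
    """

    direction: Derivation
    chromosome_lengths: dict[str, int]
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    biased: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            lab = np.asarray(self.biased[chrom], dtype=bool)
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions on {chrom} not strictly increasing")
            if pos.size != lab.size:
                raise ValueError(f"positions/labels length mismatch on {chrom}")
            self.positions[chrom] = pos
            self.biased[chrom] = lab

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    @property
    def n_substitutions(self) -> int:
        return int(sum(p.size for p in self.positions.values()))


def _is_base(b: str) -> bool:
    return b in ACGT


def call_snds(
    columns: Iterable[AlignedColumn],
    context_half_width: int = 5,
) -> list[SubstitutionRecord]:
    """Identify SNDs and apply the 11-bp context filters.

    A record is emitted for every column where target and query both carry an
    unambiguous base and differ.  ``passed_filters`` is set to ``False`` when,
    inside the window of ``2 * context_half_width + 1`` aligned columns centred
    on the SND, (i) any gap occurs in either sequence, (ii) more than two
    target/query differences occur (the focal SND counts as one of them), or
    (iii) the outgroup base is absent at the SND column.  Windows truncated by
    a chromosome or alignment-block edge are discarded as well.

    Input columns must be ordered by (chromosome, position); unsorted input
    raises ``ValueError``.
    """
    w = context_half_width
    cols: list[AlignedColumn] = []
    seen_chroms: set[str] = set()
    last_chrom: str | None = None
    last_pos = -1
    for col in columns:
        col = col.normalized()
        if col.chromosome != last_chrom:
            if col.chromosome in seen_chroms:
                raise ValueError(
                    f"input not grouped by chromosome: {col.chromosome} reappears"
                )
            seen_chroms.add(col.chromosome)
            last_chrom = col.chromosome
            last_pos = -1
        else:
            if col.target_base != GAP and col.position <= last_pos:
                raise ValueError(
                    f"unsorted input at {col.chromosome}:{col.position}"
                )
        if col.target_base != GAP:
            last_pos = col.position
        cols.append(col)

    n_total = len(cols)
    records: list[SubstitutionRecord] = []
    n_fail = {"edge": 0, "gap": 0, "dense": 0, "outgroup": 0}
    for i, col in enumerate(cols):
        tb, qb = col.target_base, col.query_base
        if tb == GAP or qb == GAP:
            continue
        if not (_is_base(tb) and _is_base(qb)) or tb == qb:
            continue
        window = cols[max(0, i - w) : i + w + 1]
        ok = True
        if len(window) < 2 * w + 1 or any(
            c.chromosome != col.chromosome for c in window
        ):
            ok = False
            n_fail["edge"] += 1
        elif any(c.target_base == GAP or c.query_base == GAP for c in window):
            ok = False
            n_fail["gap"] += 1
        else:
            expected = list(range(col.position - w, col.position + w + 1))
            if [c.position for c in window] != expected:
                ok = False  # block boundary inside the window
                n_fail["edge"] += 1
            else:
                diffs = sum(
                    1
                    for c in window
                    if _is_base(c.target_base)
                    and _is_base(c.query_base)
                    and c.target_base != c.query_base
                )
                if diffs > 2:
                    ok = False
                    n_fail["dense"] += 1
                elif col.outgroup_base is None or not _is_base(col.outgroup_base):
                    ok = False
                    n_fail["outgroup"] += 1
        records.append(
            SubstitutionRecord(
                chromosome=col.chromosome,
                position=col.position,
                target_base=tb,
                query_base=qb,
                outgroup_base=col.outgroup_base
                if col.outgroup_base and _is_base(col.outgroup_base)
                else None,
                passed_filters=ok,
            )
        )
    logger.info(
        "call_snds: %d columns, %d SND candidates, discarded per rule: "
        "edge=%d gap=%d dense=%d outgroup=%d",
        n_total,
        len(records),
        n_fail["edge"],
        n_fail["gap"],
        n_fail["dense"],
        n_fail["outgroup"],
    )
    return records


def polarize(record: SubstitutionRecord) -> SubstitutionRecord:
    """Assign the derivation direction and the weak-to-strong (biased) label.

    The target/query base matching the outgroup is taken as ancestral; the
    other lineage carries the derived base.  When neither matches, the record
    is inconclusive and carries ``biased=False``.
    """
    if not record.passed_filters:
        raise ValueError("polarize requires a record that passed the filters")
    og = record.outgroup_base
    if og is None:
        raise ValueError("polarize requires an outgroup base")
    if record.target_base == og:
        derivation = Derivation.QUERY
        derived = record.query_base
    elif record.query_base == og:
        derivation = Derivation.TARGET
        derived = record.target_base
    else:
        return replace(record, derivation=Derivation.INCONCLUSIVE, biased=False)
    biased = og in WEAK and derived in STRONG
    return replace(record, derivation=derivation, biased=biased)


def build_catalog(
    records: Sequence[SubstitutionRecord],
    direction: Derivation,
    chromosome_lengths: Mapping[str, int] | None = None,
) -> SubstitutionCatalog:
    """Collect polarized records of one direction into a catalog.

    Only records with ``passed_filters`` and the requested conclusive
    direction are retained.  Exact duplicates are merged; a duplicated
    position with conflicting bias labels raises ``ValueError``.
    """
    if direction is Derivation.INCONCLUSIVE:
        raise ValueError("catalogs are built per conclusive direction")
    per_chrom: dict[str, dict[int, bool]] = {}
    for rec in records:
        if not rec.passed_filters or rec.derivation is not direction:
            continue
        slot = per_chrom.setdefault(rec.chromosome, {})
        if rec.position in slot and slot[rec.position] != rec.biased:
            raise ValueError(
                f"conflicting bias labels at {rec.chromosome}:{rec.position}"
            )
        slot[rec.position] = rec.biased
    positions = {}
    biased = {}
    for chrom, slot in per_chrom.items():
        pos = np.array(sorted(slot), dtype=np.int64)
        positions[chrom] = pos
        biased[chrom] = np.array([slot[p] for p in pos], dtype=bool)
    if chromosome_lengths is None:
        chromosome_lengths = {
            chrom: int(pos[-1]) + 1 for chrom, pos in positions.items()
        }
    return SubstitutionCatalog(
        direction=direction,
        chromosome_lengths=dict(chromosome_lengths),
        positions=positions,
        biased=biased,
    )
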