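"""Readers and writers for the TSV/MAF interchange formats.

Everything is plain text for auditability: three-way alignment columns and
substitution catalogs as TSV, UBCS profiles as a BED-like TSV, summaries as
JSON.  Floats are serialized with ``repr`` so profile round-trips are
lossless.
"""

from __future__ import annotations

import json
import logging
import math
import os
import tempfile
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import yaml
from Bio import AlignIO

from .core import RegionStat, UBCSProfile
from .snd import AlignedColumn, Derivation, SubstitutionCatalog, SubstitutionRecord

logger = logging.getLogger(__name__)

THREEWAY_COLUMNS = ("chromosome", "position", "target_base", "query_base", "outgroup_base")
PROFILE_COLUMNS = (
    "chromosome",
    "region_start",
    "region_end",
    "n_subs",
    "p_hat",
    "observed",
    "expected",
    "ubcs",
    "partial",
)


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_threeway_tsv(path: str | Path) -> Iterator[AlignedColumn]:
    """Stream aligned columns from a three-way TSV.

    Columns: chromosome, position, target_base, query_base, outgroup_base,
    with "." marking an absent outgroup base; a header row is optional.
    Rows must be grouped by chromosome with nondecreasing positions.
    """
    last_chrom: str | None = None
    last_pos = -1
    seen: set[str] = set()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "chromosome":
                continue
            if len(fields) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, tb, qb, ob = fields
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad position {pos_s!r}") from exc
            if pos < 0:
                raise ValueError(f"{path}:{lineno}: negative position")
            if chrom != last_chrom:
                if chrom in seen:
                    raise ValueError(f"{path}:{lineno}: chromosome {chrom} reappears")
                seen.add(chrom)
                last_chrom, last_pos = chrom, -1
            elif pos < last_pos:
                raise ValueError(f"{path}:{lineno}: unsorted position {pos}")
            last_pos = pos
            og = None if ob in (".", "", "-") else ob
            yield AlignedColumn(chrom, pos, tb, qb, og).normalized()


def read_maf(
    path: str | Path,
    target_prefix: str | None = None,
    query_prefix: str | None = None,
) -> Iterator[AlignedColumn]:
    """Stream target/query aligned columns from a pairwise MAF.

    Each block must contain the target sequence first and the query second
    (or be identifiable by the given ``species.chrom`` prefixes).  Columns are
    yielded in target-coordinate order; gap columns are preserved so the SND
    caller can apply its indel filter.  Blocks that run backwards or overlap
    on the target raise ``ValueError``.
    """
    last: dict[str, int] = {}
    for block in AlignIO.parse(str(path), "maf"):
        recs = list(block)
        if len(recs) < 2:
            raise ValueError("MAF block with fewer than two sequences")
        trec = qrec = None
        if target_prefix or query_prefix:
            for rec in recs:
                if target_prefix and rec.id.startswith(target_prefix):
                    trec = rec
                if query_prefix and rec.id.startswith(query_prefix):
                    qrec = rec
        if trec is None:
            trec = recs[0]
        if qrec is None:
            qrec = recs[1] if recs[1] is not trec else recs[0]
        if trec.annotations.get("strand", 1) != 1:
            raise ValueError("target sequence must be on the + strand")
        chrom = trec.id.split(".", 1)[1] if "." in trec.id else trec.id
        start = int(trec.annotations["start"])
        if chrom in last and start < last[chrom]:
            raise ValueError(
                f"MAF blocks out of order or overlapping on target {chrom} at {start}"
            )
        tpos = start
        for tb, qb in zip(str(trec.seq), str(qrec.seq)):
            yield AlignedColumn(chrom, tpos, tb, qb, None).normalized()
            if tb != "-":
                tpos += 1
        last[chrom] = tpos


def attach_outgroup(
    columns: Iterable[AlignedColumn],
    outgroup: Mapping[tuple[str, int], str],
) -> Iterator[AlignedColumn]:
    """Join outgroup bases (keyed by (chromosome, position)) onto a column
    stream, e.g. one read from a MAF."""
    from dataclasses import replace

    for col in columns:
        og = outgroup.get((col.chromosome, col.position))
        yield replace(col, outgroup_base=og)


def outgroup_map_from_threeway(path: str | Path) -> dict[tuple[str, int], str]:
    """Outgroup lookup table extracted from a three-way TSV."""
    out = {}
    for col in read_threeway_tsv(path):
        if col.outgroup_base is not None:
            out[(col.chromosome, col.position)] = col.outgroup_base
    return out


def write_catalog(catalog: SubstitutionCatalog, path: str | Path,
                  records: Iterable[SubstitutionRecord] | None = None) -> None:
    """Write a catalog TSV: chromosome, position, derived_base,
    ancestral_base, direction, biased.  Chromosome lengths go into header
    comments.  Base columns are "." unless the originating records are
    supplied (the catalog itself stores only positions and labels)."""
    bases: dict[tuple[str, int], tuple[str, str]] = {}
    if records is not None:
        for rec in records:
            if rec.derived_base is not None:
                bases[(rec.chromosome, rec.position)] = (
                    rec.derived_base,
                    rec.ancestral_base,
                )
    lines = [f"#direction\t{catalog.direction.value}"]
    for chrom, length in catalog.chromosome_lengths.items():
        lines.append(f"#length\t{chrom}\t{length}")
    lines.append(
        "chromosome\tposition\tderived_base\tancestral_base\tdirection\tbiased"
    )
    for chrom in catalog.positions:
        pos = catalog.positions[chrom]
        lab = catalog.biased[chrom]
        for p, b in zip(pos, lab):
            der, anc = bases.get((chrom, int(p)), (".", "."))
            lines.append(
                f"{chrom}\t{int(p)}\t{der}\t{anc}\t{catalog.direction.value}\t{int(b)}"
            )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_catalog(path: str | Path) -> SubstitutionCatalog:
    """Read a catalog TSV written by :func:`write_catalog`."""
    direction = None
    lengths: dict[str, int] = {}
    positions: dict[str, list[int]] = {}
    biased: dict[str, list[bool]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#direction"):
                direction = Derivation(line.split("\t")[1])
                continue
            if line.startswith("#length"):
                _, chrom, length = line.split("\t")
                lengths[chrom] = int(length)
                continue
            if line.startswith("chromosome"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields")
            chrom, pos, _, _, dirn, bias = fields
            if direction is None:
                direction = Derivation(dirn)
            positions.setdefault(chrom, []).append(int(pos))
            biased.setdefault(chrom, []).append(bool(int(bias)))
    if direction is None:
        raise ValueError(f"{path}: empty catalog with no direction header")
    if not lengths:
        lengths = {c: (max(p) + 1 if p else 1) for c, p in positions.items()}
    return SubstitutionCatalog(
        direction=direction,
        chromosome_lengths=lengths,
        positions={c: np.asarray(p, dtype=np.int64) for c, p in positions.items()},
        biased={c: np.asarray(b, dtype=bool) for c, b in biased.items()},
    )


def write_profile(profile: UBCSProfile, path: str | Path) -> None:
    """Write a UBCS profile as a BED-like TSV (lossless float round-trip)."""
    lines = [f"#direction\t{profile.direction}"]
    if profile.label:
        lines.append(f"#label\t{profile.label}")
    lines.append("\t".join(PROFILE_COLUMNS))
    for regs in profile.regions.values():
        for r in regs:
            p_hat = "nan" if r.p_hat is None else repr(float(r.p_hat))
            lines.append(
                "\t".join(
                    [
                        r.chromosome,
                        str(r.start),
                        str(r.end),
                        str(r.n_subs),
                        p_hat,
                        str(r.observed),
                        repr(float(r.expected)),
                        repr(float(r.ubcs)),
                        str(int(r.partial)),
                    ]
                )
            )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_profile(path: str | Path) -> UBCSProfile:
    """Read a profile TSV written by :func:`write_profile`."""
    direction = ""
    label = ""
    regions: dict[str, list[RegionStat]] = {}
    with Path(path).open() as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#direction"):
                direction = line.split("\t")[1]
                continue
            if line.startswith("#label"):
                label = line.split("\t")[1]
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != PROFILE_COLUMNS:
                    missing = set(PROFILE_COLUMNS) - set(fields)
                    raise ValueError(
                        f"{path}:{lineno}: profile header mismatch; missing {sorted(missing)}"
                    )
                header_seen = True
                continue
            if len(fields) != len(PROFILE_COLUMNS):
                raise ValueError(f"{path}:{lineno}: wrong field count")
            chrom = fields[0]
            p_hat = float(fields[4])
            regions.setdefault(chrom, []).append(
                RegionStat(
                    chromosome=chrom,
                    start=int(fields[1]),
                    end=int(fields[2]),
                    n_subs=int(fields[3]),
                    p_hat=None if math.isnan(p_hat) else p_hat,
                    observed=int(fields[5]),
                    expected=float(fields[6]),
                    ubcs=float(fields[7]),
                    partial=bool(int(fields[8])),
                )
            )
    return UBCSProfile(direction=direction, regions=regions, label=label)


def write_json(obj, path: str | Path) -> None:
    _atomic_write(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (may be empty)."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
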