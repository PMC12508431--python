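"""Enhancer locus ingestion and preparation.

Enhancer loci arrive as BED intervals anchored on the binding summit of the
fusion oncoprotein that defines them.  Two preparation steps happen before any
signal is quantified: intervals shorter than a minimum width (600 bp by
default) are extended so that occupancy around the binding site is assessed
over a comparable footprint, and each locus is assigned the gene whose
transcription start site lies nearest its anchor ("nearest promoter" linkage).

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "EnhancerLocus",
    "TSSRecord",
    "BedParseError",
    "ValidationError",
    "read_bed",
    "read_tss_bed",
    "read_chrom_sizes",
    "extend_to_min_width",
    "link_to_nearest_tss",
    "write_linked_bed",
]


class BedParseError(ValueError):
    """A BED-like line could not be parsed; the message names the line."""


class ValidationError(ValueError):
    """Coordinates violate an invariant (bounds, widths, chromosome sizes)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class EnhancerLocus:
    """An enhancer interval with an anchor point and an optional linked gene.

    The anchor is the functional center of the locus (the fusion-protein peak
    summit); it defaults to the interval midpoint and is the reference point
    for minimum-width extension, tornado windows and TSS linkage.
    """

    id: str
    interval: GenomicInterval
    anchor: int = -1
    linked_gene: str | None = None
    linked_distance: int | None = None

    def __post_init__(self) -> None:
        if self.anchor < 0:
            object.__setattr__(
                self, "anchor", (self.interval.start + self.interval.end) // 2
            )
        if not (self.interval.start <= self.anchor < self.interval.end):
            raise ValidationError(
                f"anchor {self.anchor} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end} "
                f"for locus {self.id}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: the promoter-proximal point of a gene."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"negative TSS {self.tss} for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r} for {self.gene_id}")


def _check_chrom_bounds(
    interval: GenomicInterval, chrom_sizes: Mapping[str, int] | None, context: str
) -> None:
    if chrom_sizes is None:
        return
    size = chrom_sizes.get(interval.chrom)
    if size is None:
        raise ValidationError(f"{context}: unknown chromosome {interval.chrom}")
    if interval.end > size:
        raise ValidationError(
            f"{context}: interval {interval.chrom}:{interval.start}-{interval.end} "
            f"exceeds chromosome length {size}"
        )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV into a name -> length map."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from exc
    return sizes


def _parse_bed_line(
    line: str, lineno: int, path: str
) -> tuple[str, int, int, str | None, str | None] | None:
    line = line.rstrip("\n")
    if not line or line.startswith(("#", "track", "browser")):
        return None
    fields = line.split("\t")
    if len(fields) < 3:
        raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start < 0 or start >= end:
        raise BedParseError(
            f"{path}:{lineno}: invalid interval {chrom}:{start}-{end} (start >= end)"
        )
    name = fields[3] if len(fields) >= 4 and fields[3] not in (".", "") else None
    strand = fields[5] if len(fields) >= 6 else None
    return chrom, start, end, name, strand


def read_bed(
    path: str | Path, chrom_sizes: Mapping[str, int] | None = None
) -> list[EnhancerLocus]:
    """Read enhancer loci from BED3/BED4/BED6.

    Locus ids come from column 4 when present, else ``chrom:start-end``.
    Anchors default to interval midpoints.  File order is preserved.
    """
    loci: list[EnhancerLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parsed = _parse_bed_line(line, lineno, str(path))
            if parsed is None:
                continue
            chrom, start, end, name, _ = parsed
            interval = GenomicInterval(chrom, start, end)
            _check_chrom_bounds(interval, chrom_sizes, f"{path}:{lineno}")
            loci.append(
                EnhancerLocus(id=name or f"{chrom}:{start}-{end}", interval=interval)
            )
    ids = [loc.id for loc in loci]
    if len(set(ids)) != len(ids):
        dupes = {i for i in ids if ids.count(i) > 1}
        raise ValidationError(f"{path}: duplicate locus ids {sorted(dupes)[:5]}")
    return loci


def read_tss_bed(path: str | Path) -> list[TSSRecord]:
    """Read TSS records from BED6: the TSS is `start` on + and `end-1` on -."""
    records: list[TSSRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parsed = _parse_bed_line(line, lineno, str(path))
            if parsed is None:
                continue
            chrom, start, end, name, strand = parsed
            if name is None:
                raise BedParseError(f"{path}:{lineno}: TSS BED requires a gene id")
            strand = strand or "+"
            tss = start if strand == "+" else end - 1
            records.append(TSSRecord(gene_id=name, chrom=chrom, tss=tss, strand=strand))
    genes = [r.gene_id for r in records]
    if len(set(genes)) != len(genes):
        raise ValidationError(f"{path}: duplicate gene ids in TSS annotation")
    return records


def extend_to_min_width(
    loci: Sequence[EnhancerLocus],
    min_width: int = 600,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[EnhancerLocus]:
    """Extend loci narrower than ``min_width`` to exactly ``min_width``.

    The width deficit is split floor/ceil to the left/right of the interval.
    Clipping at position 0 or at the chromosome end moves the lost bases to
    the other side, so the output width equals ``min_width`` whenever the
    chromosome permits.  Anchors are never moved; wide loci pass unchanged.
    """
    if min_width <= 0:
        raise ValueError(f"min_width must be positive, got {min_width}")
    out: list[EnhancerLocus] = []
    for locus in loci:
        iv = locus.interval
        if iv.width >= min_width:
            out.append(locus)
            continue
        chrom_len = None if chrom_sizes is None else chrom_sizes.get(iv.chrom)
        if chrom_len is not None and chrom_len < min_width:
            raise ValidationError(
                f"chromosome {iv.chrom} (length {chrom_len}) shorter than "
                f"min_width {min_width}; cannot extend locus {locus.id}"
            )
        deficit = min_width - iv.width
        start = iv.start - deficit // 2
        end = iv.end + (deficit - deficit // 2)
        if start < 0:  # clipped left: push the lost bases right
            end -= start
            start = 0
        if chrom_len is not None and end > chrom_len:  # clipped right: push left
            start -= end - chrom_len
            end = chrom_len
            start = max(start, 0)
        out.append(replace(locus, interval=GenomicInterval(iv.chrom, start, end)))
    return out


def link_to_nearest_tss(
    loci: Sequence[EnhancerLocus], tss: Sequence[TSSRecord]
) -> list[EnhancerLocus]:
    """Assign each locus the gene whose TSS is nearest its anchor.

    Distance is |TSS - anchor| on the same chromosome; exact-distance ties go
    to the lexicographically smallest gene id.  Loci on chromosomes with no
    TSS are returned unlinked with a logged warning.
    """
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {r.chrom for r in tss}:
        recs = sorted(
            (r for r in tss if r.chrom == chrom), key=lambda r: (r.tss, r.gene_id)
        )
        by_chrom[chrom] = (
            np.array([r.tss for r in recs], dtype=np.int64),
            [r.gene_id for r in recs],
        )
    out: list[EnhancerLocus] = []
    for locus in loci:
        entry = by_chrom.get(locus.chrom)
        if entry is None:
            logger.warning(
                "locus %s: no TSS on chromosome %s; left unlinked",
                locus.id,
                locus.chrom,
            )
            out.append(locus)
            continue
        positions, genes = entry
        i = int(np.searchsorted(positions, locus.anchor))
        candidates = []
        if i > 0:
            candidates.append(abs(int(positions[i - 1]) - locus.anchor))
        if i < len(positions):
            candidates.append(abs(int(positions[i]) - locus.anchor))
        best = min(candidates)
        # all TSS at exactly distance `best` compete; smallest gene_id wins
        tied: list[str] = []
        for pos in {locus.anchor - best, locus.anchor + best}:
            lo = int(np.searchsorted(positions, pos, side="left"))
            hi = int(np.searchsorted(positions, pos, side="right"))
            tied.extend(genes[lo:hi])
        out.append(
            replace(locus, linked_gene=min(tied), linked_distance=best)
        )
    return out


def write_linked_bed(loci: Iterable[EnhancerLocus], path: str | Path) -> None:
    """Write loci as BED6+2 (name, 0, ., linked_gene, distance)."""
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.interval
            gene = locus.linked_gene if locus.linked_gene is not None else "."
            dist = locus.linked_distance if locus.linked_distance is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{locus.id}\t0\t.\t{gene}\t{dist}\n"
            )
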