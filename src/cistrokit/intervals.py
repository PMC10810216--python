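"""Genomic intervals, BED I/O, and overlap machinery.

All coordinates are 0-based half-open (BED convention). The "center" of an
interval is ``floor((start + end) / 2)``; windows derived from centers are
even-width, so the floor never introduces asymmetric ties downstream.

Chromosome names are compared as exact strings: ``chr1`` and ``1`` are
different chromosomes. :func:`chromosome_mismatch_warning` reports names
present in only one of two sets so silent naming mismatches surface early.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence


class BedParseError(ValueError):
    """Raised for malformed BED records; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Shared base pairs with ``other``; 0 when on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def center_window(iv: GenomicInterval, halfwidth: int) -> GenomicInterval:
    """Window of ±halfwidth bp around the interval center, clipped at 0."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    c = iv.center
    return GenomicInterval(
        iv.chrom, max(0, c - halfwidth), c + halfwidth, iv.strand, iv.name
    )


@dataclass
class PeakSet:
    """An ordered collection of intervals, e.g. one factor's cistrome."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def sorted(self) -> "PeakSet":
        return PeakSet(sorted(self.intervals, key=GenomicInterval.sort_key), self.label)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        for ivs in out.values():
            ivs.sort(key=GenomicInterval.sort_key)
        return out

    def chromosomes(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def covered_bp(self) -> int:
        """Total bases covered by the union of the intervals."""
        return sum(iv.width for iv in merge(self).intervals)


@dataclass
class OverlapResult:
    """Hit counts and index pairs from comparing two interval sets."""

    n_a: int
    n_b: int
    n_a_hit: int
    n_b_hit: int
    pairs: list[tuple[int, int]]

    @property
    def n_a_only(self) -> int:
        return self.n_a - self.n_a_hit

    @property
    def n_b_only(self) -> int:
        return self.n_b - self.n_b_hit


def overlap(a: PeakSet, b: PeakSet, min_bp: int = 1) -> OverlapResult:
    """Count intervals of each set overlapped by >= min_bp bases of the other.

    Sweep over start-sorted intervals per chromosome; an A interval is "hit"
    when it shares at least ``min_bp`` bases with at least one B interval.
    Default ``min_bp=1`` corresponds to direct overlap with no threshold.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    a_idx: dict[str, list[tuple[GenomicInterval, int]]] = {}
    b_idx: dict[str, list[tuple[GenomicInterval, int]]] = {}
    for store, peaks in ((a_idx, a), (b_idx, b)):
        for i, iv in enumerate(peaks):
            store.setdefault(iv.chrom, []).append((iv, i))
    for store in (a_idx, b_idx):
        for lst in store.values():
            lst.sort(key=lambda t: t[0].sort_key())

    pairs: list[tuple[int, int]] = []
    a_hit: set[int] = set()
    b_hit: set[int] = set()
    for chrom, a_list in a_idx.items():
        b_list = b_idx.get(chrom)
        if not b_list:
            continue
        start_ptr = 0
        active: list[tuple[GenomicInterval, int]] = []
        for iv_a, i_a in a_list:
            while start_ptr < len(b_list) and b_list[start_ptr][0].start < iv_a.end:
                active.append(b_list[start_ptr])
                start_ptr += 1
            # drop B intervals that can no longer overlap anything (ends before
            # the current A start); A list is start-sorted so this is safe
            active = [t for t in active if t[0].end > iv_a.start]
            for iv_b, i_b in active:
                if iv_a.overlap_bp(iv_b) >= min_bp:
                    pairs.append((i_a, i_b))
                    a_hit.add(i_a)
                    b_hit.add(i_b)
    pairs.sort()
    return OverlapResult(len(a), len(b), len(a_hit), len(b_hit), pairs)


def merge(a: PeakSet) -> PeakSet:
    """Union of overlapping or bookended intervals, per chromosome."""
    merged: list[GenomicInterval] = []
    for chrom in sorted(a.chromosomes()):
        ivs = sorted(
            (iv for iv in a if iv.chrom == chrom), key=GenomicInterval.sort_key
        )
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # bookended intervals merge too
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return PeakSet(merged, a.label)


def chromosome_mismatch_warning(a: PeakSet, b: PeakSet) -> list[str]:
    """Chromosome names present in exactly one of the two sets."""
    return sorted(a.chromosomes() ^ b.chromosomes())


def read_bed(path) -> PeakSet:
    """Read BED3/BED6 into a PeakSet, preserving coordinates verbatim."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in {".", ""}:
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, name, score)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals)


def write_bed(path, peaks: PeakSet) -> None:
    """Write BED; emits 3 columns when no interval carries name/score/strand."""
    bed6 = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in peaks
    )
    with open(path, "w") as fh:
        for iv in peaks:
            if bed6:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                    f"\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
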