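"""Genomic interval algebra and BED-family file I/O.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers bases ``start`` .. ``end - 1``.  Chromosome names are
compared as opaque strings ("chr1" and "1" are distinct).  These conventions
hold for every downstream stage.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "SignalTrack",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "merge_within",
    "overlaps",
    "region_signal",
]

_VALID_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Raised on malformed BED-family lines; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open region on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class IntervalSet:
    """A collection of intervals from one sample / one mark.

    ``merged=True`` asserts intervals are pairwise disjoint and sorted; this
    is checked at construction.  ``constituent_counts`` (parallel to
    ``intervals``) records how many input intervals each merged region
    absorbed, when produced by :func:`merge_within`.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    sample_id: str = ""
    mark: str = "other"
    merged: bool = False
    constituent_counts: list[int] | None = None

    def __post_init__(self) -> None:
        if self.merged:
            s = self.sorted_intervals()
            if [iv.sort_key() for iv in self.intervals] != [
                iv.sort_key() for iv in s
            ]:
                raise ValueError("merged IntervalSet must be sorted")
            for a, b in zip(s, s[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ValueError(
                        f"merged IntervalSet must be disjoint: {a} overlaps {b}"
                    )
        if self.constituent_counts is not None and len(
            self.constituent_counts
        ) != len(self.intervals):
            raise ValueError("constituent_counts length mismatch")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def sorted_intervals(self) -> list[GenomicInterval]:
        return sorted(self.intervals, key=GenomicInterval.sort_key)

    def sorted(self) -> "IntervalSet":
        """A sorted view (new IntervalSet; file order is not kept)."""
        return replace(
            self, intervals=self.sorted_intervals(), constituent_counts=None
        )

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def widths(self) -> np.ndarray:
        return np.array([iv.width for iv in self.intervals], dtype=int)


@dataclass
class SignalTrack:
    """Piecewise-constant non-negative signal (coverage / fold enrichment).

    Stored per chromosome as parallel ``starts``/``ends``/``values`` arrays,
    sorted and disjoint, for O(log n) interval queries.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    sample_id: str = ""

    @classmethod
    def from_intervals(
        cls,
        intervals: Sequence[GenomicInterval],
        values: Sequence[float],
        sample_id: str = "",
    ) -> "SignalTrack":
        if len(intervals) != len(values):
            raise ValueError("intervals and values length mismatch")
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, v in zip(intervals, values):
            v = float(v)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"signal values must be finite and >= 0, got {v}")
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, v))
        data = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            vals = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"track intervals overlap on {chrom}")
            data[chrom] = (starts, ends, vals)
        return cls(data=data, sample_id=sample_id)

    def chroms(self) -> list[str]:
        return sorted(self.data)


def _parse_line(
    fields: list[str], fmt: str, lineno: int
) -> GenomicInterval:
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >= 3 columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start = int(fields[1])
        end = int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score: float | None = None
    strand = "."
    if fmt in ("narrowPeak", "broadPeak"):
        # col 7 (index 6) is signalValue in both ENCODE formats
        if len(fields) > 6:
            try:
                score = float(fields[6])
            except ValueError as exc:
                raise BedParseError(
                    f"line {lineno}: non-numeric signalValue"
                ) from exc
        if len(fields) > 5 and fields[5] in _VALID_STRANDS:
            strand = fields[5]
    else:
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-numeric score") from exc
        if len(fields) > 5 and fields[5] in _VALID_STRANDS:
            strand = fields[5]
    try:
        return GenomicInterval(chrom, start, end, name, score, strand)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from exc


def read_bed(
    path: str | Path,
    format: str = "bed",
    sample_id: str = "",
    mark: str = "other",
) -> IntervalSet:
    """Read BED3/BED6, narrowPeak or broadPeak into an :class:`IntervalSet`.

    File order is preserved (use ``.sorted()`` for the sorted view).  Empty
    files give an empty set; ``track``/``browser``/``#`` lines are skipped
    with a logged warning; malformed lines raise :class:`BedParseError`
    naming the line.
    """
    if format not in ("bed", "narrowPeak", "broadPeak"):
        raise ValueError(f"unknown format {format!r}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                logger.warning("%s line %d: skipping header line", path, lineno)
                continue
            intervals.append(_parse_line(line.split("\t"), format, lineno))
    return IntervalSet(intervals=intervals, sample_id=sample_id, mark=mark)


def write_bed(regions: IntervalSet | Sequence[GenomicInterval], path: str | Path) -> None:
    """Write BED6; ``read_bed`` of the output reproduces coordinates exactly."""
    ivs = regions.intervals if isinstance(regions, IntervalSet) else list(regions)
    with open(path, "w") as fh:
        for iv in ivs:
            name = iv.name if iv.name is not None else "."
            score = "." if iv.score is None else repr(float(iv.score))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_bedgraph(path: str | Path, sample_id: str = "") -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`."""
    intervals: list[GenomicInterval] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                logger.warning("%s line %d: skipping header line", path, lineno)
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(
                    f"line {lineno}: bedGraph needs 4 columns, got {len(fields)}"
                )
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                val = float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
            intervals.append(iv)
            values.append(val)
    return SignalTrack.from_intervals(intervals, values, sample_id=sample_id)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            starts, ends, vals = track.data[chrom]
            for s, e, v in zip(starts, ends, vals):
                fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def merge_within(
    regions: IntervalSet | Sequence[GenomicInterval], gap: int = 0
) -> IntervalSet:
    """Merge intervals whose separation is <= ``gap`` bp (transitive closure).

    Bookended intervals merge at ``gap=0``.  Output is disjoint, sorted, and
    records each region's constituent count.  Idempotent for any fixed gap.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    ivs = regions.intervals if isinstance(regions, IntervalSet) else list(regions)
    meta = regions if isinstance(regions, IntervalSet) else None
    out: list[GenomicInterval] = []
    counts: list[int] = []
    for iv in sorted(ivs, key=GenomicInterval.sort_key):
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end <= gap:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = replace(prev, end=iv.end)
            counts[-1] += 1
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
            counts.append(1)
    return IntervalSet(
        intervals=out,
        sample_id=meta.sample_id if meta else "",
        mark=meta.mark if meta else "other",
        merged=True,
        constituent_counts=counts,
    )


def overlaps(
    a: IntervalSet | Sequence[GenomicInterval],
    b: IntervalSet | Sequence[GenomicInterval],
    min_overlap: int = 1,
    min_fraction: float = 0.0,
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Flag which intervals of ``a`` overlap any interval of ``b``.

    Returns ``(hit, pairs)`` where ``hit[i]`` is True iff some ``b[j]`` on the
    same chromosome shares at least ``min_overlap`` bases (and at least
    ``min_fraction`` of the shorter interval, if given) with ``a[i]``, and
    ``pairs`` lists every qualifying ``(i, j, overlap_bp)``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    a_ivs = a.intervals if isinstance(a, IntervalSet) else list(a)
    b_ivs = b.intervals if isinstance(b, IntervalSet) else list(b)
    hit = np.zeros(len(a_ivs), dtype=bool)
    pairs: list[tuple[int, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b_ivs):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for rows in by_chrom.values():
        rows.sort()
    for i, iv in enumerate(a_ivs):
        rows = by_chrom.get(iv.chrom)
        if not rows:
            continue
        starts = [r[0] for r in rows]
        # candidates: b-intervals starting before a's end; scan left for overlap
        hi = bisect.bisect_left(starts, iv.end)
        for s, e, j in rows[:hi]:
            ov = min(iv.end, e) - max(iv.start, s)
            if ov >= min_overlap:
                shorter = min(iv.width, e - s)
                if ov >= min_fraction * shorter:
                    hit[i] = True
                    pairs.append((i, j, ov))
    pairs.sort()
    return hit, pairs


def region_signal(
    track: SignalTrack, region: GenomicInterval, mode: str = "area"
) -> float:
    """Signal in a region: ``area`` = sum(overlap bp x value); ``mean`` = area / width.

    Uncovered bases contribute 0.
    """
    if mode not in ("area", "mean"):
        raise ValueError(f"mode must be 'area' or 'mean', got {mode!r}")
    entry = track.data.get(region.chrom)
    area = 0.0
    if entry is not None:
        starts, ends, vals = entry
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if hi > lo:
            s = np.maximum(starts[lo:hi], region.start)
            e = np.minimum(ends[lo:hi], region.end)
            area = float(np.sum((e - s) * vals[lo:hi]))
    return area / region.width if mode == "mean" else area


def concat(sets: Iterable[IntervalSet]) -> IntervalSet:
    """Concatenate interval sets (metadata dropped, order preserved)."""
    intervals: list[GenomicInterval] = []
    for s in sets:
        intervals.extend(s.intervals)
    return IntervalSet(intervals=intervals)
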