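"""Genome and interval primitives.

All coordinates are 0-based, half-open (BED convention).  Intervals on
different chromosomes have *undefined* distance, reported as ``None`` so
callers must handle the case explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered set of chromosomes with their lengths in bp."""

    chrom_lengths: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chrom_lengths]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        for name, length in self.chrom_lengths:
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeIndex":
        return cls(tuple(d.items()))

    @property
    def chroms(self) -> list[str]:
        return [c for c, _ in self.chrom_lengths]

    def length(self, chrom: str) -> int:
        for c, n in self.chrom_lengths:
            if c == chrom:
                return n
        raise ValidationError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.chrom_lengths)

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.length(chrom) // bin_size)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A called ChIP peak as consumed from a peak caller (FDR-thresholded
    upstream; this package never calls peaks from reads)."""

    interval: GenomicInterval
    summit: int
    enrichment: float
    fdr: float

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError("summit outside peak interval")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError("fdr outside [0, 1]")
        if self.enrichment < 0:
            raise ValidationError("negative enrichment")


def as_interval(x) -> GenomicInterval:
    return x.interval if isinstance(x, Peak) else x


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Gap in bp between two intervals on the same chromosome (0 when they
    share at least one base, and book-ended intervals have gap 0); ``None``
    when the intervals lie on different chromosomes."""
    a, b = as_interval(a), as_interval(b)
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def point_interval_distance(pos: int, iv: GenomicInterval) -> int:
    """Distance from a point to an interval: 0 if the point lies inside."""
    if iv.start <= pos < iv.end:
        return 0
    if pos < iv.start:
        return iv.start - pos
    return pos - (iv.end - 1)


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge into a sorted, pairwise-disjoint set.  Book-ended intervals
    (gap 0) are merged; ``gap`` > 0 additionally bridges short gaps."""
    ivs = sorted((as_interval(x) for x in intervals), key=lambda v: (v.chrom, v.start, v.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def genome_fraction_covered(
    intervals: Iterable[GenomicInterval], genome: GenomeIndex
) -> float:
    merged = merge_intervals(intervals)
    for iv in merged:
        if iv.chrom not in genome:
            raise ValidationError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > genome.length(iv.chrom):
            raise ValidationError(f"interval exceeds chromosome {iv.chrom!r}")
    covered = sum(iv.length for iv in merged)
    return covered / genome.total_length


class IntervalIndex:
    """Per-chromosome sorted-array index over disjoint (merged) intervals,
    supporting point membership, point→interval distance and overlap queries.

    Built on numpy searchsorted; intervals are merged on construction so
    binary search over starts/ends is sufficient (no tree needed, and we
    also require nearest-distance queries which interval trees lack).
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        merged = merge_intervals(intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in merged:
            self._starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[attr-defined]
            self._ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[attr-defined]
        for c in self._starts:
            self._starts[c] = np.asarray(self._starts[c], dtype=np.int64)
            self._ends[c] = np.asarray(self._ends[c], dtype=np.int64)

    def contains(self, chrom: str, pos) -> np.ndarray | bool:
        """Membership of point(s) in any interval."""
        pos_arr = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if chrom not in self._starts:
            res = np.zeros(pos_arr.shape, dtype=bool)
        else:
            starts, ends = self._starts[chrom], self._ends[chrom]
            i = np.searchsorted(starts, pos_arr, side="right") - 1
            res = (i >= 0) & (pos_arr < ends[np.clip(i, 0, len(ends) - 1)])
        return res if np.ndim(pos) else bool(res[0])

    def distance(self, chrom: str, pos) -> np.ndarray | float:
        """Point→nearest-interval distance (0 inside); inf when the
        chromosome carries no interval."""
        pos_arr = np.atleast_1d(np.asarray(pos, dtype=np.int64)).astype(float)
        if chrom not in self._starts:
            res = np.full(pos_arr.shape, np.inf)
        else:
            starts, ends = self._starts[chrom], self._ends[chrom]
            i = np.searchsorted(starts, pos_arr, side="right") - 1
            left = np.where(
                i >= 0,
                np.where(
                    pos_arr < ends[np.clip(i, 0, len(ends) - 1)],
                    0.0,
                    pos_arr - (ends[np.clip(i, 0, len(ends) - 1)] - 1),
                ),
                np.inf,
            )
            j = np.clip(i + 1, 0, len(starts) - 1)
            right = np.where(i + 1 < len(starts), starts[j] - pos_arr, np.inf)
            res = np.minimum(left, right)
        return res if np.ndim(pos) else float(res[0])


class PointIndex:
    """Sorted point set (e.g. TSS positions) with nearest-distance queries."""

    def __init__(self, points: Sequence[tuple[str, int]]):
        self._pos: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[int]] = {}
        for chrom, p in points:
            by_chrom.setdefault(chrom, []).append(p)
        for c, ps in by_chrom.items():
            self._pos[c] = np.asarray(sorted(ps), dtype=np.int64)

    def distance(self, chrom: str, pos) -> np.ndarray | float:
        pos_arr = np.atleast_1d(np.asarray(pos, dtype=np.int64)).astype(float)
        if chrom not in self._pos:
            res = np.full(pos_arr.shape, np.inf)
        else:
            pts = self._pos[chrom]
            i = np.searchsorted(pts, pos_arr)
            left = np.where(i > 0, pos_arr - pts[np.clip(i - 1, 0, len(pts) - 1)], np.inf)
            right = np.where(i < len(pts), pts[np.clip(i, 0, len(pts) - 1)] - pos_arr, np.inf)
            res = np.minimum(np.abs(left), np.abs(right))
        return res if np.ndim(pos) else float(res[0])

    def interval_distance(self, chrom: str, start: int, end: int) -> float:
        """Distance from a half-open interval to the nearest point (0 when a
        point lies inside the interval)."""
        if chrom not in self._pos:
            return float("inf")
        pts = self._pos[chrom]
        i = int(np.searchsorted(pts, start))
        if i < len(pts) and pts[i] <= end - 1:
            return 0.0
        d = float("inf")
        if i > 0:
            d = min(d, float(start - pts[i - 1]))
        if i < len(pts):
            d = min(d, float(pts[i] - (end - 1)))
        return d
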