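"""Binned genome coverage tracks: 1x normalisation, input subtraction,
window averaging, CpG-density tracks and heatmap-style signal matrices.

A track holds one fixed-width bin array per chromosome (default 50 bp).
Values may be negative after input subtraction; that sign information is
kept in the track and only clipped by :func:`threshold_log` for log-scale
display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, IncompatibilityError, ValidationError
from .genome import GenomeIndex


@dataclass
class CoverageTrack:
    genome: GenomeIndex
    bin_size: int
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        for chrom in self.genome.chroms:
            n = self.genome.n_bins(chrom, self.bin_size)
            if chrom not in self.data or len(self.data[chrom]) != n:
                raise ValidationError(f"bin array for {chrom!r} has wrong length")

    @classmethod
    def zeros(cls, genome: GenomeIndex, bin_size: int = 50) -> "CoverageTrack":
        data = {
            c: np.zeros(genome.n_bins(c, bin_size), dtype=np.float64)
            for c in genome.chroms
        }
        return cls(genome, bin_size, data)

    @classmethod
    def from_arrays(cls, genome, bin_size, data) -> "CoverageTrack":
        return cls(genome, bin_size, {c: np.asarray(v, dtype=np.float64) for c, v in data.items()})

    @property
    def n_bins_total(self) -> int:
        return sum(len(v) for v in self.data.values())

    def global_mean(self) -> float:
        return sum(float(v.sum()) for v in self.data.values()) / self.n_bins_total

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            self.genome, self.bin_size, {c: v * factor for c, v in self.data.items()}
        )

    def bin_midpoints(self, chrom: str) -> np.ndarray:
        n = len(self.data[chrom])
        return np.arange(n) * self.bin_size + self.bin_size / 2.0

    def same_grid(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.genome.chrom_lengths == other.genome.chrom_lengths
        )


def normalize_1x(track: CoverageTrack) -> CoverageTrack:
    """Scale by a single global factor so the genome-wide mean bin value is
    exactly 1 (coverage-based 1x normalisation)."""
    mean = track.global_mean()
    if mean == 0.0:
        raise DegenerateInputError("cannot 1x-normalize an all-zero track")
    return track.scaled(1.0 / mean)


def subtract_input(chip: CoverageTrack, input_track: CoverageTrack) -> CoverageTrack:
    """Elementwise chip − input; negative values are preserved."""
    if not chip.same_grid(input_track):
        raise IncompatibilityError("tracks differ in genome or bin size")
    return CoverageTrack(
        chip.genome,
        chip.bin_size,
        {c: chip.data[c] - input_track.data[c] for c in chip.genome.chroms},
    )


def _window_bin_range(center: float, width: float, bin_size: int, n_bins: int):
    """Indices of bins whose midpoint lies in [center - width/2,
    center + width/2), clipped to the chromosome."""
    lo = center - width / 2.0
    hi = center + width / 2.0
    i0 = math.ceil(lo / bin_size - 0.5)
    i1 = math.ceil(hi / bin_size - 0.5)
    return max(i0, 0), min(i1, n_bins)


def window_mean(
    track: CoverageTrack, chrom: str, center: int, width: int = 2000
) -> float:
    """Mean of bin values whose midpoints fall in the window; truncated at
    chromosome ends so only existing bins are averaged."""
    if chrom not in track.genome:
        raise ValidationError(f"unknown chromosome {chrom!r}")
    arr = track.data[chrom]
    i0, i1 = _window_bin_range(center, width, track.bin_size, len(arr))
    if i0 >= i1:
        raise ValidationError("window lies entirely off the chromosome")
    return float(arr[i0:i1].mean())


def window_means(
    track: CoverageTrack, loci: Sequence[tuple[str, int]], width: int = 2000
) -> np.ndarray:
    """Vectorised :func:`window_mean` over many (chrom, center) loci."""
    out = np.empty(len(loci))
    cumsums = {c: np.concatenate([[0.0], np.cumsum(v)]) for c, v in track.data.items()}
    for k, (chrom, center) in enumerate(loci):
        if chrom not in track.genome:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        cs = cumsums[chrom]
        i0, i1 = _window_bin_range(center, width, track.bin_size, len(cs) - 1)
        if i0 >= i1:
            raise ValidationError("window lies entirely off the chromosome")
        out[k] = (cs[i1] - cs[i0]) / (i1 - i0)
    return out


def cpg_density_track(
    fasta, genome: GenomeIndex, bin_size: int = 50
) -> CoverageTrack:
    """Per-bin CpG density in percent: 100 × (CG dinucleotide starts whose
    first base lies in the bin) / bin_size, case-insensitive; dinucleotides
    containing N never match.  A CG straddling a bin boundary is credited to
    the bin holding its C."""
    data = {}
    for chrom in genome.chroms:
        if chrom not in fasta:
            raise ValidationError(f"chromosome {chrom!r} missing from FASTA")
        seq = str(fasta[chrom][:]).upper()
        if len(seq) != genome.length(chrom):
            raise ValidationError(f"FASTA/index length mismatch for {chrom!r}")
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        cg_start = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        n = genome.n_bins(chrom, bin_size)
        counts = np.bincount(
            np.nonzero(cg_start)[0] // bin_size, minlength=n
        ).astype(np.float64)
        data[chrom] = 100.0 * counts / bin_size
    return CoverageTrack(genome, bin_size, data)


@dataclass
class SignalMatrix:
    """Loci × window-bins matrix for heatmap-style displays; truncated
    windows are padded with NaN, which every downstream mean/correlation
    excludes."""

    loci: list[tuple[str, int]]
    flank: int
    bin_size: int
    values: np.ndarray
    sort_key: str = "input_order"

    def row_means(self) -> np.ndarray:
        return np.nanmean(self.values, axis=1)


def build_signal_matrix(
    track: CoverageTrack,
    loci: Sequence[tuple[str, int]],
    flank: int = 3000,
    sort_by: Optional[np.ndarray] = None,
    sort_key: str = "input_order",
    descending: bool = True,
) -> SignalMatrix:
    if flank % track.bin_size != 0:
        raise ValidationError("flank must be a multiple of bin_size")
    bs = track.bin_size
    ncol = 2 * flank // bs
    values = np.full((len(loci), ncol), np.nan)
    for r, (chrom, center) in enumerate(loci):
        if chrom not in track.genome:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        arr = track.data[chrom]
        start_bin = math.ceil((center - flank) / bs - 0.5)
        for j in range(ncol):
            b = start_bin + j
            if 0 <= b < len(arr):
                values[r, j] = arr[b]
    order = np.arange(len(loci))
    if sort_by is not None:
        key = np.asarray(sort_by)
        order = np.argsort(-key if descending else key, kind="stable")
        values = values[order]
    sorted_loci = [loci[i] for i in order]
    return SignalMatrix(sorted_loci, flank, bs, values, sort_key)


def threshold_log(x, floor: float = 0.0):
    """log2(1 + max(x, floor)) — clips input-subtracted negatives for
    log-scale display."""
    return np.log2(1.0 + np.maximum(x, floor))
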