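"""Accessible-TSS and putative-enhancer calling from normalised,
input-subtracted ATAC and Pol II tracks.

A TSS is accessible when any bin within 1 kb carries ATAC signal above
threshold.  Putative enhancers are runs of bins jointly above the ATAC and
Pol II thresholds whose bin midpoints lie more than 2 kb from every
annotated TSS; thresholds and merging behaviour are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IncompatibilityError, ValidationError
from .genome import GenomicInterval, PointIndex
from .tracks import CoverageTrack


@dataclass
class EnhancerCall:
    interval: GenomicInterval
    midpoint: int
    mean_atac: float
    mean_polII: float
    tss_distance: float


def call_accessible_tss(
    atac: CoverageTrack,
    chrom: str,
    pos: int,
    threshold: float = 10.0,
    radius: int = 1000,
) -> bool:
    """True iff any bin whose midpoint lies within ±radius bp of the TSS
    exceeds the ATAC threshold."""
    if chrom not in atac.genome:
        raise ValidationError(f"unknown chromosome {chrom!r}")
    if not (0 <= pos < atac.genome.length(chrom)):
        raise ValidationError(f"TSS {pos} off chromosome {chrom!r}")
    mids = atac.bin_midpoints(chrom)
    sel = np.abs(mids - pos) <= radius
    return bool((atac.data[chrom][sel] > threshold).any())


def call_enhancers(
    atac: CoverageTrack,
    polII: CoverageTrack,
    tss_points: list[tuple[str, int]],
    atac_threshold: float = 10.0,
    polII_threshold: float = 5.0,
    tss_min_dist: int = 2000,
    merge_gap: int = 0,
    min_width_bins: int = 1,
    region_mean_thresholds: bool = False,
) -> list[EnhancerCall]:
    """Select bins with ATAC > atac_threshold AND Pol II > polII_threshold
    AND bin-midpoint distance to the nearest TSS > tss_min_dist; merge
    adjacent selected bins (gap tolerance ``merge_gap`` bins) into regions.

    With ``region_mean_thresholds`` the signal thresholds are re-applied to
    region means instead of single bins after a permissive bin-level pass.
    """
    if not atac.same_grid(polII):
        raise IncompatibilityError("ATAC and Pol II tracks differ in grid")
    tss_index = PointIndex(tss_points)
    bs = atac.bin_size
    calls: list[EnhancerCall] = []
    for chrom in atac.genome.chroms:
        a, p = atac.data[chrom], polII.data[chrom]
        mids = atac.bin_midpoints(chrom)
        far = tss_index.distance(chrom, mids.astype(int)) > tss_min_dist
        mask = (a > atac_threshold) & (p > polII_threshold) & far
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            continue
        # split into runs with gaps larger than merge_gap bins
        breaks = np.nonzero(np.diff(idx) > merge_gap + 1)[0]
        for run in np.split(idx, breaks + 1):
            if len(run) < min_width_bins:
                continue
            b0, b1 = int(run[0]), int(run[-1])
            start = b0 * bs
            end = min((b1 + 1) * bs, atac.genome.length(chrom))
            mean_a = float(a[b0 : b1 + 1].mean())
            mean_p = float(p[b0 : b1 + 1].mean())
            if region_mean_thresholds and not (
                mean_a > atac_threshold and mean_p > polII_threshold
            ):
                continue
            mid = (start + end) // 2
            calls.append(
                EnhancerCall(
                    GenomicInterval(chrom, start, end),
                    mid,
                    mean_a,
                    mean_p,
                    float(tss_index.distance(chrom, mid)),
                )
            )
    return calls
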