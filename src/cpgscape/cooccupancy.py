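"""Peak colocalisation and co-occupancy statistics.

Colocalisation uses the maximum-gap convention (default 1 kb): two peaks
are colocalised when the gap between their intervals does not exceed the
threshold.  Multi-set Venn decompositions are component-based: peaks are
clustered under the transitive closure of the gap relation so chained
peaks are counted once, and each component is labelled with the set of
peak-set names it contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import DegenerateInputError, ValidationError
from .genome import (
    GenomeIndex,
    GenomicInterval,
    IntervalIndex,
    PointIndex,
    Peak,
    as_interval,
    genome_fraction_covered,
    merge_intervals,
)
from .tracks import CoverageTrack, window_means


# -------------------------------------------------------------- colocalise

@dataclass
class ColocResult:
    pairs: list[tuple[int, int]]
    n_a_hit: int
    n_b_hit: int


def colocalise(a_peaks: Sequence, b_peaks: Sequence, max_gap: int = 1000) -> ColocResult:
    """All (i, j) index pairs with gap <= max_gap, plus per-set counts of
    peaks having at least one partner."""
    a_ivs = [as_interval(p) for p in a_peaks]
    b_ivs = [as_interval(p) for p in b_peaks]
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b_ivs):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    pairs: list[tuple[int, int]] = []
    a_hit = np.zeros(len(a_ivs), dtype=bool)
    b_hit = np.zeros(len(b_ivs), dtype=bool)
    for chrom, items in by_chrom.items():
        items.sort()
        starts = np.array([s for s, _, _ in items])
        ends = np.array([e for _, e, _ in items])
        idx = np.array([j for _, _, j in items])
        for i, iv in enumerate(a_ivs):
            if iv.chrom != chrom:
                continue
            cand = np.nonzero((starts <= iv.end + max_gap) & (ends >= iv.start - max_gap))[0]
            for c in cand:
                pairs.append((i, int(idx[c])))
                a_hit[i] = True
                b_hit[idx[c]] = True
    pairs.sort()
    return ColocResult(pairs, int(a_hit.sum()), int(b_hit.sum()))


# --------------------------------------------------------------- multi_venn

@dataclass
class VennComponent:
    interval: GenomicInterval
    members: dict[str, list[int]]

    @property
    def label(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class VennResult:
    counts: dict[frozenset[str], int]
    components: list[VennComponent]

    def count(self, *names: str) -> int:
        return self.counts.get(frozenset(names), 0)

    def to_json_dict(self) -> dict[str, int]:
        return {
            "&".join(sorted(k)): v
            for k, v in sorted(self.counts.items(), key=lambda kv: "&".join(sorted(kv[0])))
        }


def multi_venn(peak_sets: dict[str, Sequence], max_gap: int = 1000) -> VennResult:
    """Cluster all peaks from all sets under the <= max_gap relation (a
    single left-to-right sweep is exact for intervals) and count
    components per label."""
    if len(peak_sets) < 2:
        raise ValidationError("multi_venn needs at least two peak sets")
    entries = []
    for name, peaks in peak_sets.items():
        for i, p in enumerate(peaks):
            iv = as_interval(p)
            entries.append((iv.chrom, iv.start, iv.end, name, i))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    components: list[VennComponent] = []
    cur_chrom, cur_start, cur_end, cur_members = None, 0, -(10**18), {}
    for chrom, start, end, name, i in entries:
        if chrom == cur_chrom and start <= cur_end + max_gap:
            cur_end = max(cur_end, end)
            cur_members.setdefault(name, []).append(i)
        else:
            if cur_members:
                components.append(
                    VennComponent(GenomicInterval(cur_chrom, cur_start, cur_end), cur_members)
                )
            cur_chrom, cur_start, cur_end = chrom, start, end
            cur_members = {name: [i]}
    if cur_members:
        components.append(
            VennComponent(GenomicInterval(cur_chrom, cur_start, cur_end), cur_members)
        )
    counts: dict[frozenset[str], int] = {}
    for comp in components:
        counts[comp.label] = counts.get(comp.label, 0) + 1
    return VennResult(counts, components)


# ------------------------------------------------- high-confidence regions

def high_confidence_regions(
    peak_sets: dict[str, Sequence[Peak]], percentile: float = 10.0
) -> list[GenomicInterval]:
    """Per set, keep peaks in the most highly enriched ``percentile`` (ties
    at the threshold included), then merge the union into a non-redundant
    interval set."""
    keep: list[GenomicInterval] = []
    for name, peaks in peak_sets.items():
        if len(peaks) == 0:
            raise ValidationError(f"peak set {name!r} is empty")
        scores = np.array([p.enrichment for p in peaks])
        thr = np.percentile(scores, 100.0 - percentile)
        keep.extend(p.interval for p, s in zip(peaks, scores) if s >= thr)
    return merge_intervals(keep)


# --------------------------------------------------------- overrepresentation

@dataclass
class OverrepResult:
    k: int
    n: int
    f: float
    fold: float
    p: float
    log10_p: float


def binomial_upper_tail_log10(k: int, n: int, f: float) -> float:
    """log10 P(X >= k), X ~ Binomial(n, f), via log-space summation."""
    if k <= 0:
        return 0.0
    ks = np.arange(k, n + 1)
    return float(logsumexp(stats.binom.logpmf(ks, n, f)) / np.log(10.0))


def overrepresentation(
    k: int, n: int, regions: Iterable[GenomicInterval], genome: GenomeIndex
) -> OverrepResult:
    """Fold-enrichment (k/n)/f of peak hits in a target-region set covering
    genome fraction f, with a one-sided (upper tail) binomial p-value."""
    if not (0 <= k <= n):
        raise ValidationError("need 0 <= k <= n")
    regions = list(regions)
    if not regions:
        raise DegenerateInputError("empty target-region set")
    f = genome_fraction_covered(regions, genome)
    if f == 0.0:
        raise DegenerateInputError("target regions cover zero genome fraction")
    fold = (k / n) / f
    log10_p = binomial_upper_tail_log10(k, n, f)
    return OverrepResult(k, n, f, fold, 10.0**log10_p, log10_p)


def fold_overrepresentation(k: int, n: int, f: float) -> float:
    """(k/n)/f for pre-computed genome fraction f."""
    if not (0 <= k <= n) or not (0 < f <= 1):
        raise ValidationError("need 0 <= k <= n and 0 < f <= 1")
    return (k / n) / f


# ------------------------------------------------------- mutual exclusivity

@dataclass
class QuadrantResult:
    threshold_a: float
    threshold_b: float
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    odds_ratio: float


def _haldane_or(a: float, b: float, c: float, d: float) -> float:
    """ad/bc with the Haldane–Anscombe +0.5 continuity correction applied
    to all cells when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def mutual_exclusivity(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    loci: Sequence[tuple[str, int]],
    threshold_a: float | None = None,
    threshold_b: float | None = None,
    width: int = 2000,
    threshold_percentile: float = 75.0,
) -> QuadrantResult:
    """Quadrant counts of per-locus 2-kb window means of two signals.

    With no explicit thresholds the per-track 75th percentile over the loci
    is used; an odds ratio far below 1 indicates mutual exclusivity."""
    if len(loci) < 4:
        raise ValidationError("need at least 4 loci")
    mean_a = window_means(track_a, loci, width)
    mean_b = window_means(track_b, loci, width)
    ta = float(np.percentile(mean_a, threshold_percentile)) if threshold_a is None else threshold_a
    tb = float(np.percentile(mean_b, threshold_percentile)) if threshold_b is None else threshold_b
    hi_a = mean_a > ta
    hi_b = mean_b > tb
    n_both = int((hi_a & hi_b).sum())
    n_a = int((hi_a & ~hi_b).sum())
    n_b = int((~hi_a & hi_b).sum())
    n_no = int((~hi_a & ~hi_b).sum())
    return QuadrantResult(ta, tb, n_both, n_a, n_b, n_no, _haldane_or(n_both, n_a, n_b, n_no))


def contingency_odds_ratio(table) -> tuple[float, float]:
    """Odds ratio (Haldane-corrected on zero cells) and two-sided exact
    conditional (Fisher/hypergeometric) p-value for a 2×2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("need a 2x2 table of non-negative integers")
    if t.sum() == 0:
        raise ValidationError("all-zero table")
    odds = _haldane_or(t[0, 0], t[0, 1], t[1, 0], t[1, 1])
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return odds, float(p)


# --------------------------------------------------------------- allocation

@dataclass
class AllocationResult:
    counts: dict[str, int]
    proportions: dict[str, float]
    poisson_se: dict[str, float]
    total: int


ALLOCATION_CATEGORIES = ("CGI_TSS", "nonCGI_TSS", "enhancer", "other")


def allocate_complexes(
    representative: Sequence,
    tss_records: Sequence,
    enhancers: Sequence,
    tss_dist: int = 1000,
    max_gap: int = 1000,
) -> AllocationResult:
    """Assign each representative peak/region the first matching category:
    CGI TSS (within tss_dist of a CGI-flagged TSS), non-CGI TSS, enhancer
    (gap <= max_gap to an enhancer call), else other.  Error bars follow
    Poisson counting statistics, se = sqrt(count)/total."""
    if len(representative) == 0:
        raise ValidationError("empty representative set")
    from .genome import interval_distance

    cgi_tss = PointIndex([(t.chrom, t.pos) for t in tss_records if t.is_cgi])
    other_tss = PointIndex([(t.chrom, t.pos) for t in tss_records if not t.is_cgi])
    enh_ivs = [e.interval if hasattr(e, "interval") else as_interval(e) for e in enhancers]
    counts = {c: 0 for c in ALLOCATION_CATEGORIES}
    for region in representative:
        iv = as_interval(region)
        if cgi_tss.interval_distance(iv.chrom, iv.start, iv.end) < tss_dist:
            counts["CGI_TSS"] += 1
        elif other_tss.interval_distance(iv.chrom, iv.start, iv.end) < tss_dist:
            counts["nonCGI_TSS"] += 1
        elif any(
            (g := interval_distance(iv, e)) is not None and g <= max_gap
            for e in enh_ivs
        ):
            counts["enhancer"] += 1
        else:
            counts["other"] += 1
    total = len(representative)
    return AllocationResult(
        counts,
        {c: counts[c] / total for c in counts},
        {c: float(np.sqrt(counts[c])) / total for c in counts},
        total,
    )
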