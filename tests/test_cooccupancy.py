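"""Colocalisation, Venn decomposition, enrichment and exclusivity
statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from cpgscape.cooccupancy import (
    allocate_complexes,
    binomial_upper_tail_log10,
    colocalise,
    contingency_odds_ratio,
    fold_overrepresentation,
    high_confidence_regions,
    multi_venn,
    mutual_exclusivity,
    overrepresentation,
)
from cpgscape.classify import TSSRecord
from cpgscape.errors import DegenerateInputError, ValidationError
from cpgscape.genome import GenomeIndex, GenomicInterval, Peak, interval_distance
from cpgscape.tracks import CoverageTrack


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def random_peakset(rng, n, span=200_000, max_len=800):
    starts = rng.integers(0, span, n)
    lens = rng.integers(50, max_len, n)
    return [iv(int(s), int(s + l)) for s, l in zip(starts, lens)]


def brute_force_pairs(a, b, max_gap):
    return sorted(
        (i, j)
        for i, av in enumerate(a)
        for j, bv in enumerate(b)
        if (d := interval_distance(av, bv)) is not None and d <= max_gap
    )


def brute_force_components(named_sets, max_gap):
    """Connected components of the gap graph via direct pairwise closure."""
    nodes = [(name, i) for name, peaks in named_sets.items() for i in range(len(peaks))]
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (na, ia), (nb, ib) in itertools.combinations(nodes, 2):
        d = interval_distance(named_sets[na][ia], named_sets[nb][ib])
        if d is not None and d <= max_gap:
            parent[find((na, ia))] = find((nb, ib))
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n[0])
    labels = {}
    for members in comps.values():
        key = frozenset(members)
        labels[key] = labels.get(key, 0) + 1
    return labels


class TestColocalise:
    def test_within_gap(self):
        res = colocalise([iv(100, 200)], [iv(900, 1000)])
        assert res.pairs == [(0, 0)] and res.n_a_hit == 1

    def test_beyond_gap(self):
        res = colocalise([iv(100, 200)], [iv(1701, 1800)])
        assert res.pairs == [] and res.n_a_hit == 0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = random_peakset(rng, 40), random_peakset(rng, 40)
        ab = colocalise(a, b)
        ba = colocalise(b, a)
        assert sorted((j, i) for i, j in ab.pairs) == ba.pairs
        assert (ab.n_a_hit, ab.n_b_hit) == (ba.n_b_hit, ba.n_a_hit)

    def test_matches_exhaustive_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            a, b = random_peakset(rng, 60), random_peakset(rng, 60)
            res = colocalise(a, b)
            assert res.pairs == brute_force_pairs(a, b, 1000)


class TestMultiVenn:
    def test_identical_single_peak_sets(self):
        res = multi_venn({"A": [iv(100, 200)], "B": [iv(100, 200)]})
        assert res.counts == {frozenset({"A", "B"}): 1}

    def test_disjoint_distant_peaks(self):
        res = multi_venn({"A": [iv(100, 200)], "B": [iv(50_000, 50_100)]})
        assert res.count("A") == 1 and res.count("B") == 1

    def test_chain_is_transitive(self):
        # a1 - b1 - a2 with consecutive gaps <= max_gap -> one {A, B} component
        res = multi_venn({"A": [iv(0, 100), iv(2000, 2100)], "B": [iv(1000, 1100)]})
        assert res.counts == {frozenset({"A", "B"}): 1}

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        sets = {name: random_peakset(rng, 50) for name in "ABC"}
        res = multi_venn(sets)
        n_peaks = sum(len(m) for comp in res.components for m in comp.members.values())
        assert n_peaks == 150
        assert sum(res.counts.values()) == len(res.components)

    def test_matches_bruteforce_components(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            sets = {name: random_peakset(rng, 30, span=60_000) for name in "AB"}
            assert multi_venn(sets).counts == brute_force_components(sets, 1000)

    def test_needs_two_sets(self):
        with pytest.raises(ValidationError):
            multi_venn({"A": [iv(0, 10)]})


class TestHighConfidence:
    def peaks(self, scores):
        return [
            Peak(iv(1000 * i, 1000 * i + 100), 1000 * i + 50, float(s), 0.001)
            for i, s in enumerate(scores)
        ]

    def test_top_decile_of_distinct_scores(self):
        regions = high_confidence_regions({"A": self.peaks(range(1, 101))})
        assert len(regions) == 10  # peaks scored 91..100, all disjoint

    def test_ties_at_threshold_kept(self):
        regions = high_confidence_regions({"A": self.peaks([5.0] * 30)})
        assert len(regions) == 30

    def test_two_sets_merge_union(self):
        a = self.peaks(range(1, 101))
        b = [
            Peak(iv(1000 * i + 50, 1000 * i + 150), 1000 * i + 60, float(s), 0.001)
            for i, s in enumerate(range(1, 101))
        ]
        regions = high_confidence_regions({"A": a, "B": b})
        # per-base mask oracle over the two top-decile lists
        mask = np.zeros(200_000, dtype=bool)
        for p in a[90:] + b[90:]:
            mask[p.interval.start : p.interval.end] = True
        assert sum(r.length for r in regions) == int(mask.sum())

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            high_confidence_regions({"A": []})


class TestOverrepresentation:
    def test_reproduces_166_fold(self):
        assert fold_overrepresentation(444, 1673, 0.0016) == pytest.approx(165.9, abs=0.05)

    def test_unenriched_fold_near_one(self):
        n, f = 5000, 0.01
        assert fold_overrepresentation(round(n * f), n, f) == pytest.approx(1.0)

    def test_exact_enumeration_small(self):
        # P(X >= 3), X ~ Binomial(10, 0.1) by direct enumeration
        expected = sum(
            math.comb(10, i) * 0.1**i * 0.9 ** (10 - i) for i in range(3, 11)
        )
        got = 10.0 ** binomial_upper_tail_log10(3, 10, 0.1)
        assert got == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0702, abs=5e-5)

    def test_full_result_object(self):
        g = GenomeIndex.from_dict({"chr1": 1_000_000})
        res = overrepresentation(40, 100, [iv(0, 1600)], g)
        assert res.f == 0.0016
        assert res.fold == pytest.approx((40 / 100) / 0.0016)
        assert res.p <= 1.0 and res.log10_p < -50

    def test_empty_regions_rejected(self):
        g = GenomeIndex.from_dict({"chr1": 1000})
        with pytest.raises(DegenerateInputError):
            overrepresentation(1, 10, [], g)


class TestContingency:
    def test_balanced_table(self):
        odds, _ = contingency_odds_ratio([[10, 10], [10, 10]])
        assert odds == 1.0

    def test_hand_arithmetic(self):
        odds, _ = contingency_odds_ratio([[20, 5], [5, 20]])
        assert odds == 16.0

    def test_zero_cell_haldane(self):
        odds, _ = contingency_odds_ratio([[10, 0], [5, 20]])
        assert odds == pytest.approx((10.5 * 20.5) / (0.5 * 5.5))

    def test_p_matches_hypergeometric_enumeration(self):
        """Two-sided exact p equals explicit enumeration over all tables
        with the same margins (point-probability rule)."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = rng.integers(0, 8, (2, 2))
            if t.sum() == 0:
                continue
            a, b, c, d = t.ravel()
            n, r1, c1 = a + b + c + d, a + b, a + c
            p_obs = sps.hypergeom.pmf(a, n, r1, c1)
            enum = sum(
                sps.hypergeom.pmf(x, n, r1, c1)
                for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
                if sps.hypergeom.pmf(x, n, r1, c1) <= p_obs * (1 + 1e-9)
            )
            _, p = contingency_odds_ratio(t)
            assert p == pytest.approx(min(enum, 1.0), rel=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            contingency_odds_ratio([[0, 0], [0, 0]])


class TestMutualExclusivity:
    def make_tracks(self, a_vals, b_vals, bin_size=50):
        g = GenomeIndex.from_dict({"chr1": len(a_vals) * bin_size})
        ta = CoverageTrack(g, bin_size, {"chr1": np.asarray(a_vals, float)})
        tb = CoverageTrack(g, bin_size, {"chr1": np.asarray(b_vals, float)})
        return ta, tb

    def test_planted_exclusive_quadrants(self):
        rng = np.random.default_rng(5)
        n_loci = 100
        a = np.zeros(n_loci * 40)
        b = np.zeros(n_loci * 40)
        loci = []
        for i in range(n_loci):
            c = i * 2000 + 1000
            loci.append(("chr1", c))
            if i % 2 == 0:
                a[i * 40 : i * 40 + 40] = 10 + rng.normal(0, 0.1)
            else:
                b[i * 40 : i * 40 + 40] = 10 + rng.normal(0, 0.1)
        ta, tb = self.make_tracks(a, b)
        q = mutual_exclusivity(ta, tb, loci)
        assert q.n_both == 0
        assert q.odds_ratio < 0.2

    def test_independent_signals_or_near_one(self):
        rng = np.random.default_rng(6)
        n_loci = 5000
        a = rng.normal(0, 1, n_loci * 40)
        b = rng.normal(0, 1, n_loci * 40)
        ta, tb = self.make_tracks(a, b)
        loci = [("chr1", i * 2000 + 1000) for i in range(n_loci)]
        q = mutual_exclusivity(ta, tb, loci)
        assert 0.75 < q.odds_ratio < 1.33

    def test_counts_partition_loci(self):
        rng = np.random.default_rng(7)
        ta, tb = self.make_tracks(rng.normal(size=4000), rng.normal(size=4000))
        loci = [("chr1", i * 2000 + 1000) for i in range(100)]
        q = mutual_exclusivity(ta, tb, loci)
        assert q.n_both + q.n_a_only + q.n_b_only + q.n_neither == 100

    def test_too_few_loci_rejected(self):
        ta, tb = self.make_tracks(np.ones(100), np.ones(100))
        with pytest.raises(ValidationError):
            mutual_exclusivity(ta, tb, [("chr1", 1000)])


class TestAllocation:
    def records(self):
        recs = [TSSRecord("g1", "t1", "chr1", 10_000, "+", is_cgi=True)]
        recs += [TSSRecord("g2", "t2", "chr1", 50_000, "+", is_cgi=False)]
        return recs

    def test_stated_se_rule(self):
        # 10 peaks, 8 at the CGI TSS: proportion 0.8, se = sqrt(8)/10
        reps = [iv(10_000 + i * 10, 10_050 + i * 10) for i in range(8)]
        reps += [iv(200_000, 200_100), iv(300_000, 300_100)]
        res = allocate_complexes(reps, self.records(), [])
        assert res.proportions["CGI_TSS"] == pytest.approx(0.8)
        assert res.poisson_se["CGI_TSS"] == pytest.approx(math.sqrt(8) / 10)

    def test_all_at_enhancers(self):
        enh = [iv(500_000, 500_300)]
        reps = [iv(500_100, 500_200), iv(499_500, 499_600)]
        res = allocate_complexes(reps, self.records(), enh)
        assert res.proportions["enhancer"] == 1.0

    def test_partition_property(self):
        rng = np.random.default_rng(8)
        reps = random_peakset(rng, 50, span=400_000)
        res = allocate_complexes(reps, self.records(), [iv(350_000, 350_500)])
        assert sum(res.counts.values()) == 50
        assert sum(res.proportions.values()) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            allocate_complexes([], self.records(), [])
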