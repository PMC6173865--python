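# Methods

`cpgscape` re-implements, as a tested pipeline, the downstream analysis
used to characterise the genomic occupancy of CFP1 (CXXC1), the
CpG-binding subunit of the Trithorax-group SET1A/B H3K4 methyltransferase
complexes: coverage-track normalisation, CpG-island (CGI) and TSS
classification, rule-based gene classes from RPKM panels, accessible-TSS
and enhancer calling, peak co-occupancy statistics, mutual-exclusivity
quantification, and a linear variance decomposition of CFP1 signal in
open chromatin.  Because the corresponding real datasets are large ChIP-,
ATAC-, DNase- and RNA-seq experiments, the package ships a synthetic
epigenome generator with planted ground truth so every stage is testable
end to end at desk scale.

## Coverage tracks

All signals are fixed-width binned tracks (default 50 bp).  1x
normalisation divides a track by a single global scalar so the
genome-wide mean bin value is exactly 1.  It is implemented on coverage
values, not via a read-count × fragment-length formula, because tracks —
not read files — are the pipeline's input; on noiseless input the two are
identical, and no read-level data are required.  Input subtraction is
elementwise on two 1x-normalised tracks on the same bin grid; negative
values are preserved in the track and clipped only by the display
transform `log2(1 + max(x, 0))`.

Window means average the bins whose *midpoints* fall in
`[center − w/2, center + w/2)` (default w = 2 kb); windows truncated at a
chromosome end average only existing bins, and heatmap-style matrices pad
truncated windows with NaN, which all downstream means and correlations
exclude.  CpG density is reported in percent per bin:
`100 × (# CG dinucleotide starts with the C inside the bin) / bin_size`
(so 5 CpGs in a 50-bp window = 10%).  A CG straddling a bin boundary is
credited to the bin containing its C; dinucleotides containing N never
match; matching is case-insensitive.

## Classification rules

A TSS is **CGI-associated** when its distance to the nearest CGI is
< 1 kb (0 when inside).  Peak summits are allocated to the first matching
category of a fixed precedence: CGI TSS (< 1 kb of a TSS and < 1 kb of a
CGI), CGI genic, CGI intergenic, non-CGI TSS, genic, intergenic — a
partition by construction.

Gene classes use a 16-tissue RPKM panel.  **Housekeeping**: RPKM ≥ 0.1 in
every tissue; sample SD (n−1) of log2 RPKM < 1; no tissue deviating from
the arithmetic tissue mean by more than 4-fold in either direction.  The
0.1 threshold is read as a *floor* for the log-scale clauses (logs are
computed on `max(rpkm, 0.1)`) while the first clause tests raw values —
the reading that keeps the first clause non-vacuous and the logs finite;
a filtering interpretation can be obtained by pre-filtering the matrix.
**Tissue-specific**: a gene is a candidate ("normally non-expressed")
when all 16 tissues are ≤ 0.1 or strictly more than 8 of 16 tissues are
≤ 10% of the panel maximum; a candidate is tissue-specific in a cell
type when its expression there (averaged over that cell type's samples —
the sample-mean convention is ours) reaches at least half the panel
maximum.  Housekeeping and tissue-specific labels are disjoint.

## Feature calls

A TSS is **accessible** when any bin with midpoint within ±1 kb exceeds
the ATAC threshold (default 10, on the normalised/subtracted scale).
**Putative enhancers** are runs of bins with ATAC > 10 and Pol II > 5
whose midpoints lie more than 2 kb from every TSS; adjacent selected bins
merge with gap tolerance 0 bins and minimum width 1 bin.  The thresholds
are applied per bin by default (a region-mean mode exists in config);
merging parameters are exposed because only the thresholds themselves are
canonical.  Region midpoint is `floor((start+end)/2)` and serves as the
locus centre for all window analyses.

## Co-occupancy statistics

Two peaks are **colocalised** when the gap between their intervals is at
most 1 kb.  Multi-set Venn counts are *component-based*: all peaks are
clustered under the transitive closure of the gap relation (for intervals
a single left-to-right sweep is exact), each connected component counts
once, and is labelled with the set of peak-set names it contains — this
makes "X of Y peaks colocalised" bookkeeping deterministic when chains
occur.  **High-confidence regions** keep, per peak set, the most highly
enriched tenth percentile (linear-interpolation percentile, ties at the
threshold included so tied top peaks are never dropped) and merge the
union.  **Overrepresentation** of k hits among n peaks in regions
covering genome fraction f is `(k/n)/f`, with a one-sided upper-tail
binomial p-value computed by log-space summation (logsumexp of log-pmf
terms), numerically exact far below the double-precision underflow of a
direct sum.  **Mutual exclusivity** classifies loci into quadrants by
2-kb window means of the two tracks against thresholds that default to
the per-track 75th percentile over the loci (the published comparison is
a density plot without stated thresholds; the quadrant odds ratio is our
quantitative proxy and the thresholds are exposed in config); the odds
ratio uses the Haldane–Anscombe +0.5 correction when any cell is empty.
2×2 association tables use the same odds ratio with a two-sided Fisher
exact p.  Complex-allocation error bars assume Poisson peak counts:
`se = sqrt(count)/total` (a binomial option exists).

## CFP1 signal model

Loci are the union of TSS points and enhancer midpoints with exact
duplicate positions removed.  Chromatin accessibility combines DNase and
ATAC 2-kb window means by z-scoring each across loci (sample SD) and
averaging, giving the assays equal weight.  The variance decomposition is
OLS of CFP1 window means on CpG density, H3K4me3 and SET1A plus
intercept, restricted to the top-decile accessibility loci (ties
included).  Reported: coefficients with standard errors, per-feature
single-regressor R² (marginal), multiple R² (joint; the "variance
explained" figure refers to multiple, not adjusted, R²), and a sequential
type-I ANOVA in the stated feature order — both sequential and marginal
partitions are emitted because either convention may be wanted.  Motif
scanning matches IUPAC consensus strings on both strands, counts
overlapping matches, counts palindromic motifs once per position, and
reports the fraction of match starts inside CGIs together with the
companion statistic, the fraction of genomic CG dinucleotides inside
CGIs.

## Synthetic epigenome

The generator is a pure function of (config, seed) via
`numpy.random.default_rng`; stage seeds are derived deterministically
from the master seed.  Default conditions: a 2-Mb genome on two
chromosomes; background sequence with ~1% CG dinucleotide starts
(iid letters with CG thinning); planted CGIs of 500–1500 bp regenerated
until they hold ≥ 10.5% CG starts; 200 genes on an ~7.8-kb slot grid with
±500 bp jitter (60 housekeeping, 20 + 20 tissue-specific, 50 silent
Polycomb, 50 variable filler), each class half CGI-promoter; 35 enhancer
sites (15 per cell type plus 5 shared) and 10 intergenic TrxG-only
sites.  The slot grid guarantees enhancers sit far (> 7 kb) from every
TSS, so planted calls can never violate the 2-kb exclusion.

Signals are Gaussian bumps (SD 150 bp at TSSs, 200 bp at enhancers,
400 bp for broad H3K27me3, and two ±500 bp bumps for the bimodal
H3K4me1 enhancer signature) over half-normal background noise (SD 1), so
raw coverage is non-negative; the input track is flat 1x plus noise so
subtraction is non-trivial.  ATAC amplitudes are ≥ 3× the calling
threshold at planted sites.  H3K27me3 appears only at silent Polycomb
TSSs, where no CFP1-complex bumps are planted — the source of the
mutual-exclusivity structure.  TrxG subunit membership per site is drawn
with conditional probabilities that plant the SET1A-complex structure
(SET1A mostly within CFP1 sites, HCF1 mostly where both are present,
RBBP5 near-ubiquitous at TrxG sites, Menin TSS-biased, UTX
enhancer-biased).

CFP1 is the planted linear response
`baseline + a·CpG% + b·H3K4me3 + c·SET1A + ε` per bin
(a = 0.5, b = 0.6, c = 0.8, baseline 6), with a per-locus amplitude noise
bump (SD 2.5) at active TSSs and enhancers; the baseline keeps the raw
track non-negative under the signed noise.  Because the pipeline's 1x
normalisation rescales each track by its own empirical mean, the truth
records the *effective* coefficients on the normalised scale
(`a/m_CFP1`, `b·m_K4/m_CFP1`, `c·m_SET/m_CFP1`, where `m` are the raw
track means) alongside the nominal ones, plus each locus's systematic
window mean and noise SD so the analytic R² of the generating model can
be computed exactly.  Input subtraction shifts only the regression
intercept.

Expression profiles are drawn per class and redrawn (bounded retries)
until the emitted values satisfy or violate exactly the intended
classification clauses, including after per-cell sample noise — planted
labels are therefore recoverable with zero errors by construction, which
is what the recovery tests assert.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level noise and mappability artefacts,
fragment-length effects, copy-number and GC biases, overlapping genes and
alternative TSSs, correlated biological replicate structure, realistic
nucleotide composition beyond CpG content, and peak-caller behaviour
(peaks are emitted directly with planted FDRs).  The tests demonstrate
correctness of the computations under the planted statistical structure,
not robustness to real-data pathologies.

## Numerical choices

Coordinates are 0-based half-open throughout; GTF converts on read.
Book-ended intervals merge.  Cross-chromosome distances are undefined
(`None`), never infinity.  Peaks without a summit column default to the
interval midpoint (floor).  Percentiles use numpy linear interpolation;
z-scores and SDs use the sample (n−1) denominator.  The binomial tail and
all odds ratios are computed as described above; degenerate inputs
(all-zero tracks, zero-variance vectors, empty region sets, rank-deficient
designs) raise typed errors rather than returning silent NaNs.

## Problem sizes

The default synthetic study (2 Mb, 200 genes, 35 enhancer sites, 13
tracks, two cell types) runs the full nine-stage pipeline in a few
seconds; the heaviest validation — 100 seeded track replicates for
regression recovery and 1000 randomised colocalisation trials against
brute-force oracles — completes in about a minute.  These sizes were
chosen so the whole validation suite is cheap to re-run while every
statistic still has enough loci (≈ 220 loci, 22 top-decile) to be
meaningfully estimated.

## Known limitations

The enhancer caller reports single-bin-resolution regions and does not
rank by H3K27ac or assign enhancers to genes.  The Venn decomposition's
component counting differs from pairwise counting when chains longer than
two peaks occur; both conventions appear in the literature and only the
component-based one is implemented.  The mutual-exclusivity odds ratio
depends on the threshold convention; defaults are documented above.  No
permutation-based overlap null (GAT/regioneR style) is provided — the
binomial model assumes independently placed peaks.
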