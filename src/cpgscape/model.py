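"""Accessibility scoring, feature correlations, the linear variance
decomposition of CFP1 signal in open chromatin, and IUPAC motif scanning.

The locus signal matrix holds one row per non-redundant locus (TSS points
plus enhancer midpoints, exact duplicate positions removed) and one column
per signal, each value a 2-kb window mean of the normalised,
input-subtracted track.  Chromatin accessibility combines DNase and ATAC
by z-scoring each across loci and averaging, so both assays carry equal
weight.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .genome import GenomicInterval, IntervalIndex
from .tracks import CoverageTrack, window_means


def accessibility_score(dnase_vals, atac_vals) -> np.ndarray:
    """Mean of the per-locus z-scores of the two accessibility signals
    (sample SD, n−1 denominator)."""
    d = np.asarray(dnase_vals, dtype=float)
    a = np.asarray(atac_vals, dtype=float)
    if d.shape != a.shape or d.ndim != 1 or len(d) < 2:
        raise ValidationError("need two equal-length vectors with >= 2 loci")
    sd_d, sd_a = d.std(ddof=1), a.std(ddof=1)
    if sd_d == 0 or sd_a == 0:
        raise DegenerateInputError("zero variance in an accessibility signal")
    return ((d - d.mean()) / sd_d + (a - a.mean()) / sd_a) / 2.0


def pearson_r2(x, y) -> tuple[float, float]:
    """Product-moment correlation R and R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValidationError("need >= 3 paired loci")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("constant vector has no defined correlation")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def select_top_accessible(scores, percentile: float = 10.0) -> np.ndarray:
    """Boolean mask of loci with accessibility score in the top
    ``percentile``; ties at the threshold are included."""
    s = np.asarray(scores, dtype=float)
    thr = np.percentile(s, 100.0 - percentile)
    return s >= thr


def build_locus_matrix(
    tracks: dict[str, CoverageTrack],
    tss_points: Sequence[tuple[str, int]],
    enhancer_midpoints: Sequence[tuple[str, int]],
    cpg_track: CoverageTrack | None = None,
    width: int = 2000,
) -> pd.DataFrame:
    """Loci × features table of 2-kb window means.  Loci are TSS points and
    enhancer midpoints with exact duplicate (chrom, pos) entries removed;
    the 'kind' column distinguishes the two sources."""
    seen: set[tuple[str, int]] = set()
    loci: list[tuple[str, int]] = []
    kinds: list[str] = []
    for kind, pts in (("TSS", tss_points), ("enhancer", enhancer_midpoints)):
        for chrom, pos in pts:
            if (chrom, pos) not in seen:
                seen.add((chrom, pos))
                loci.append((chrom, pos))
                kinds.append(kind)
    df = pd.DataFrame(
        {"chrom": [c for c, _ in loci], "pos": [p for _, p in loci], "kind": kinds}
    )
    all_tracks = dict(tracks)
    if cpg_track is not None:
        all_tracks["CpG_density"] = cpg_track
    for name, track in all_tracks.items():
        df[name] = window_means(track, loci, width)
    return df


@dataclass
class RegressionResult:
    features: list[str]
    coefficients: dict[str, float]
    intercept: float
    std_errors: dict[str, float]
    marginal_r2: dict[str, float]
    joint_r2: float
    anova: pd.DataFrame  # sequential (type-I) sum-of-squares partition

    def to_json_dict(self) -> dict:
        return {
            "features": self.features,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "std_errors": self.std_errors,
            "marginal_r2": self.marginal_r2,
            "joint_r2": self.joint_r2,
            "anova": self.anova.reset_index().to_dict(orient="records"),
        }


def variance_decomposition(
    data: pd.DataFrame, features: Sequence[str], response: str
) -> RegressionResult:
    """OLS of the response on the features plus intercept.

    Reports per-feature single-regressor R² (marginal), the multiple R²
    (joint), and a sequential ANOVA partition in the given feature order;
    both partitions are emitted because either convention may be wanted.
    """
    if len(data) < 10:
        raise ValidationError("need at least 10 loci for the decomposition")
    X = data.loc[:, list(features)].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateInputError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    coeffs = dict(zip(features, fit.params[1:]))
    ses = dict(zip(features, fit.bse[1:]))
    marginal = {}
    for j, f in enumerate(features):
        single = sm.OLS(y, sm.add_constant(X[:, [j]])).fit()
        marginal[f] = float(single.rsquared)
    # sequential sums of squares: RSS drop as each feature enters in order
    tss = float(((y - y.mean()) ** 2).sum())
    rss_prev = tss
    rows = []
    for j in range(1, len(features) + 1):
        fit_j = sm.OLS(y, sm.add_constant(X[:, :j])).fit()
        rss_j = float(fit_j.ssr)
        rows.append(
            dict(term=features[j - 1], seq_ss=rss_prev - rss_j,
                 seq_r2=(rss_prev - rss_j) / tss)
        )
        rss_prev = rss_j
    rows.append(dict(term="residual", seq_ss=rss_prev, seq_r2=rss_prev / tss))
    anova = pd.DataFrame(rows).set_index("term")
    return RegressionResult(
        list(features),
        {k: float(v) for k, v in coeffs.items()},
        float(fit.params[0]),
        {k: float(v) for k, v in ses.items()},
        marginal,
        float(fit.rsquared),
        anova,
    )


# -------------------------------------------------------------- motif scan

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement_motif(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


def _motif_regex(motif: str) -> re.Pattern:
    try:
        body = "".join(IUPAC[ch] for ch in motif.upper())
    except KeyError as e:
        raise ValidationError(f"invalid IUPAC code {e.args[0]!r}") from None
    return re.compile(f"(?=({body}))")  # lookahead: count overlapping matches


@dataclass
class MotifScanResult:
    motif: str
    n_matches: int
    n_in_cgi: int
    fraction_in_cgi: float
    cpg_fraction_in_cgi: float


def motif_scan_fraction(
    motif: str,
    fasta,
    chroms: Sequence[str],
    cgis: Iterable[GenomicInterval],
) -> MotifScanResult:
    """Scan both strands for exact IUPAC matches and report the fraction of
    match start positions falling inside CGIs, together with the companion
    statistic: the fraction of genomic CG dinucleotides inside CGIs.

    Overlapping matches count individually; a palindromic motif (equal to
    its own reverse complement) is counted once per position rather than
    once per strand.  Minus-strand matches are located by scanning the
    forward sequence with the reverse-complemented motif, so 'start' is
    always a plus-strand coordinate.
    """
    if len(motif) < 4:
        raise ValidationError("motif must be at least 4 bp")
    cgi_index = cgis if isinstance(cgis, IntervalIndex) else IntervalIndex(cgis)
    patterns = [_motif_regex(motif)]
    rc = reverse_complement_motif(motif)
    if rc.upper() != motif.upper():
        patterns.append(_motif_regex(rc))
    n_match = n_in = 0
    n_cpg = n_cpg_in = 0
    for chrom in chroms:
        seq = str(fasta[chrom][:]).upper()
        for pat in patterns:
            for m in pat.finditer(seq):
                n_match += 1
                if cgi_index.contains(chrom, m.start()):
                    n_in += 1
        for m in re.finditer("(?=CG)", seq):
            n_cpg += 1
            if cgi_index.contains(chrom, m.start()):
                n_cpg_in += 1
    if n_match == 0:
        raise DegenerateInputError(f"motif {motif!r} not found in genome")
    return MotifScanResult(
        motif, n_match, n_in, n_in / n_match,
        n_cpg_in / n_cpg if n_cpg else float("nan"),
    )
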