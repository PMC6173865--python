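"""TSS, summit and gene-class classification.

Gene classes follow the three-clause housekeeping rule and the
candidate/half-max tissue-specific rule applied to a 16-tissue RPKM panel:

* housekeeping — RPKM >= 0.1 in every tissue, sample SD of log2 RPKM < 1,
  and no tissue deviating from the arithmetic tissue mean by more than
  4-fold in either direction;
* tissue-specific — a gene normally non-expressed across the panel (all
  RPKM <= 0.1, or more than half the tissues at <= 10% of the panel
  maximum) whose expression in the target cell type reaches at least half
  that panel maximum.

Logs are taken on values floored at 0.1 so the low-expression clause stays
a separate raw-value test while log statistics remain finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome import GenomicInterval, IntervalIndex, PointIndex


def rpkm(count: float, transcript_length: int, library_size: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if transcript_length <= 0 or library_size <= 0:
        raise ValidationError("transcript length and library size must be positive")
    if count < 0:
        raise ValidationError("negative read count")
    return count / ((transcript_length / 1e3) * (library_size / 1e6))


def classify_cgi_tss(
    chrom: str, pos: int, cgis: IntervalIndex | Iterable[GenomicInterval],
    max_dist: int = 1000,
) -> bool:
    """A TSS is CGI-associated when its distance to the nearest CGI is
    < max_dist bp (0 when inside one)."""
    idx = cgis if isinstance(cgis, IntervalIndex) else IntervalIndex(cgis)
    return idx.distance(chrom, pos) < max_dist


class SummitCategory(str, Enum):
    CGI_TSS = "CGI_TSS"
    CGI_GENIC = "CGI_genic"
    CGI_INTERGENIC = "CGI_intergenic"
    TSS = "TSS"
    GENIC = "genic"
    INTERGENIC = "intergenic"


def classify_summit(
    chrom: str,
    summit: int,
    tss_index: PointIndex,
    gene_index: IntervalIndex,
    cgi_index: IntervalIndex,
    tss_dist: int = 1000,
    cgi_dist: int = 1000,
) -> SummitCategory:
    """First matching category in the fixed precedence order: CGI TSS,
    CGI genic, CGI intergenic, (non-CGI) TSS, genic, intergenic."""
    near_tss = tss_index.distance(chrom, summit) < tss_dist
    in_cgi = cgi_index.contains(chrom, summit)
    near_cgi = in_cgi or cgi_index.distance(chrom, summit) < cgi_dist
    in_gene = gene_index.contains(chrom, summit)
    if near_tss and near_cgi:
        return SummitCategory.CGI_TSS
    if in_cgi and in_gene:
        return SummitCategory.CGI_GENIC
    if in_cgi:
        return SummitCategory.CGI_INTERGENIC
    if near_tss:
        return SummitCategory.TSS
    if in_gene:
        return SummitCategory.GENIC
    return SummitCategory.INTERGENIC


@dataclass
class TSSRecord:
    gene_id: str
    transcript_id: str
    chrom: str
    pos: int
    strand: str
    is_cgi: bool = False
    is_accessible: bool = False
    gene_class: str = "other"


def _check_matrix(expr: pd.DataFrame) -> np.ndarray:
    vals = expr.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("missing RPKM value in expression matrix")
    if (vals < 0).any():
        raise ValidationError("negative RPKM value")
    return vals


def housekeeping_stats(
    expr: pd.DataFrame, rpkm_floor: float = 0.1, sd_max: float = 1.0,
    ratio_log2_max: float = 2.0,
) -> pd.DataFrame:
    """Per-gene clause evaluation for the housekeeping rule.

    expr: genes × tissues RPKM matrix.  Returns min_rpkm, sd_log2,
    max_abs_log2_ratio and the three clause flags plus the final label.
    """
    vals = _check_matrix(expr)
    floored = np.maximum(vals, rpkm_floor)
    min_rpkm = vals.min(axis=1)
    sd_log2 = np.log2(floored).std(axis=1, ddof=1)
    mean = floored.mean(axis=1)
    max_ratio = np.abs(np.log2(floored / mean[:, None])).max(axis=1)
    c1 = min_rpkm >= rpkm_floor
    c2 = sd_log2 < sd_max
    c3 = max_ratio <= ratio_log2_max
    return pd.DataFrame(
        {
            "min_rpkm": min_rpkm,
            "sd_log2": sd_log2,
            "max_abs_log2_ratio": max_ratio,
            "expressed_everywhere": c1,
            "low_variance": c2,
            "ratio_bounded": c3,
            "housekeeping": c1 & c2 & c3,
        },
        index=expr.index,
    )


def classify_housekeeping(expr: pd.DataFrame, **kw) -> pd.Series:
    return housekeeping_stats(expr, **kw)["housekeeping"]


def tissue_specific_stats(
    expr: pd.DataFrame,
    cell_expr: pd.Series,
    rpkm_floor: float = 0.1,
    low_frac: float = 0.1,
    half_max_frac: float = 0.5,
) -> pd.DataFrame:
    """Candidate ('normally non-expressed') and tissue-specific flags.

    Candidate: all tissues <= rpkm_floor OR strictly more than half of the
    tissues at <= low_frac × panel maximum.  Tissue-specific: candidate
    whose cell-type RPKM >= half_max_frac × panel maximum.
    """
    vals = _check_matrix(expr)
    missing = set(expr.index) - set(cell_expr.index)
    if missing:
        raise ValidationError(f"genes missing from cell expression: {sorted(missing)[:3]}")
    cell = cell_expr.reindex(expr.index).to_numpy(dtype=float)
    n_tissues = vals.shape[1]
    vmax = vals.max(axis=1)
    all_low = (vals <= rpkm_floor).all(axis=1)
    n_low = (vals <= low_frac * vmax[:, None]).sum(axis=1)
    mostly_low = n_low > n_tissues // 2
    candidate = all_low | mostly_low
    specific = candidate & (cell >= half_max_frac * vmax)
    return pd.DataFrame(
        {
            "max_rpkm_16": vmax,
            "cell_rpkm": cell,
            "all_low": all_low,
            "n_tissues_low": n_low,
            "candidate": candidate,
            "tissue_specific": specific,
        },
        index=expr.index,
    )


def classify_tissue_specific(expr: pd.DataFrame, cell_expr: pd.Series, **kw) -> pd.Series:
    return tissue_specific_stats(expr, cell_expr, **kw)["tissue_specific"]


def gene_classes(
    expr: pd.DataFrame, cell_expr: dict[str, pd.Series], **kw
) -> pd.Series:
    """Combined per-gene label: 'housekeeping', 'tissue_specific(<cell>)'
    or 'other'.  Housekeeping and tissue-specific are disjoint by
    construction (a housekeeping gene is never a candidate)."""
    hk = classify_housekeeping(expr)
    label = pd.Series("other", index=expr.index, dtype=object)
    for cell, ce in cell_expr.items():
        ts = classify_tissue_specific(expr, ce, **kw)
        label[ts & ~hk] = f"tissue_specific({cell})"
    label[hk] = "housekeeping"
    return label
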