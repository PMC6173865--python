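"""End-to-end orchestration of the analysis stages over a directory of
input files (as emitted by :mod:`cpgscape.simulate`, or assembled from
real data in the same formats).

Every numeric constant of the analysis lives in :class:`AnalysisConfig`;
stage logic only ever reads it from there.  The report is written as JSON
with sorted keys so identical inputs and configuration give byte-identical
output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .classify import (
    TSSRecord,
    classify_cgi_tss,
    classify_summit,
    gene_classes,
)
from .cooccupancy import (
    allocate_complexes,
    colocalise,
    high_confidence_regions,
    multi_venn,
    mutual_exclusivity,
    overrepresentation,
)
from .errors import ValidationError
from .features import call_accessible_tss, call_enhancers
from .genome import GenomicInterval, IntervalIndex, PointIndex
from .model import (
    accessibility_score,
    build_locus_matrix,
    pearson_r2,
    select_top_accessible,
    variance_decomposition,
)
from .tracks import cpg_density_track, normalize_1x, subtract_input, window_means


@dataclass
class AnalysisConfig:
    """All analysis thresholds, with the study's standard values as
    defaults."""

    bin_size: int = 50
    window: int = 2000
    atac_tss_threshold: float = 10.0
    atac_enh_threshold: float = 10.0
    polII_enh_threshold: float = 5.0
    tss_cgi_dist: int = 1000
    tss_near_dist: int = 1000
    enh_tss_dist: int = 2000
    coloc_gap: int = 1000
    top_percentile: float = 10.0
    rpkm_floor: float = 0.1
    hk_sd_max: float = 1.0
    hk_ratio_log2_max: float = 2.0
    ts_half_max_frac: float = 0.5
    ts_low_frac: float = 0.1
    fdr_threshold: float = 0.01
    regression_features: tuple[str, ...] = ("CpG_density", "H3K4me3", "SET1A")
    cell: str = "ery"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_checksums(paths) -> dict[str, str]:
    out = {}
    for p in sorted(paths):
        p = Path(p)
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    return out


def run_pipeline(sim_dir, outdir, config: AnalysisConfig | None = None) -> dict:
    """Execute the full analysis over the inputs under ``sim_dir`` and
    write ``report.json`` plus per-stage TSVs to ``outdir``.

    Stages, in order: track normalisation/subtraction; CpG density; TSS and
    summit classification; gene classes from RPKM; accessible TSSs and
    enhancer calls; peak colocalisation and enhancer overrepresentation;
    CFP1/H3K27me3 mutual exclusivity; high-confidence TrxG co-occupancy and
    allocation; locus signal matrix with correlations and the variance
    decomposition.
    """
    cfg = config or AnalysisConfig()
    sim_dir = Path(sim_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cell_dir = sim_dir / cfg.cell

    genome = cio.read_chrom_sizes(sim_dir / "genome.chrom.sizes")
    genes = cio.read_gtf(sim_dir / "genes.gtf")
    cgis = cio.read_bed(sim_dir / "cgis.bed")
    cgi_index = IntervalIndex(cgis)
    fasta = cio.open_fasta(sim_dir / "genome.fa")
    report: dict = {"config": asdict(cfg), "config_hash": cfg.config_hash()}
    report["input_checksums"] = _file_checksums(
        list(sim_dir.glob("*.tsv")) + list(sim_dir.glob("*.bed"))
        + list(sim_dir.glob("*.gtf")) + list(sim_dir.glob("*.sizes"))
    )

    # stage 1: normalisation and input subtraction -------------------------
    track_files = sorted(cell_dir.glob("*.bedgraph"))
    raw = {p.stem: cio.read_bedgraph(p, genome, cfg.bin_size) for p in track_files}
    input_norm = normalize_1x(raw["input"])
    tracks = {
        name: subtract_input(normalize_1x(t), input_norm)
        for name, t in raw.items()
        if name != "input"
    }
    report["tracks"] = {
        "n_tracks": len(tracks),
        "post_norm_means": {n: round(normalize_1x(raw[n]).global_mean(), 12) for n in sorted(raw)},
    }

    # stage 2: CpG density -------------------------------------------------
    cpg = cpg_density_track(fasta, genome, cfg.bin_size)
    report["cpg_density"] = {
        "genome_mean_percent": float(np.mean([cpg.data[c].mean() for c in genome.chroms])),
    }

    # stage 3: TSS records and CFP1 summit categories ----------------------
    gene_bodies = [
        GenomicInterval(g.chrom, g.start, g.end, g.strand, g.gene_id)
        for g in genes.itertuples()
    ]
    gene_index = IntervalIndex(gene_bodies)
    tss_points = [(g.chrom, g.tss) for g in genes.itertuples()]
    tss_index = PointIndex(tss_points)
    peaks = {
        p.stem: cio.read_narrowpeak(p) for p in sorted(cell_dir.glob("*.narrowPeak"))
    }
    peaks = {
        n: [pk for pk in ps if pk.fdr < (cfg.fdr_threshold if n != "H3K27me3" else 0.1)]
        for n, ps in peaks.items()
    }
    summit_counts: dict[str, int] = {}
    for pk in peaks["CFP1"]:
        cat = classify_summit(
            pk.interval.chrom, pk.summit, tss_index, gene_index, cgi_index,
            cfg.tss_near_dist, cfg.tss_cgi_dist,
        ).value
        summit_counts[cat] = summit_counts.get(cat, 0) + 1
    report["summits"] = {
        "n_cfp1_peaks": len(peaks["CFP1"]),
        "categories": dict(sorted(summit_counts.items())),
    }

    # stage 4: gene classes from the RPKM panel ----------------------------
    expr16 = pd.read_csv(sim_dir / "rpkm_16tissues.tsv", sep="\t", index_col=0)
    cell_expr = {}
    for cell_file in sorted(sim_dir.glob("rpkm_*.tsv")):
        cell_name = cell_file.stem.replace("rpkm_", "")
        if cell_name == "16tissues":
            continue
        cell_expr[cell_name] = pd.read_csv(cell_file, sep="\t", index_col=0).mean(axis=1)
    labels = gene_classes(
        expr16, cell_expr,
        rpkm_floor=cfg.rpkm_floor, low_frac=cfg.ts_low_frac,
        half_max_frac=cfg.ts_half_max_frac,
    )
    labels.rename("gene_class").to_csv(outdir / "gene_classes.tsv", sep="\t")
    report["gene_classes"] = labels.value_counts().sort_index().to_dict()

    # stage 5: TSS annotation, accessible TSSs, enhancers ------------------
    atac, polII = tracks["ATAC"], tracks["PolII"]
    records = []
    for g in genes.itertuples():
        records.append(
            TSSRecord(
                g.gene_id, g.transcript_id, g.chrom, g.tss, g.strand,
                is_cgi=classify_cgi_tss(g.chrom, g.tss, cgi_index, cfg.tss_cgi_dist),
                is_accessible=call_accessible_tss(
                    atac, g.chrom, g.tss, cfg.atac_tss_threshold, cfg.tss_near_dist
                ),
                gene_class=labels.get(g.gene_id, "other"),
            )
        )
    tss_df = pd.DataFrame([vars(r) for r in records])
    tss_df.to_csv(outdir / "tss_records.tsv", sep="\t", index=False)
    acc = tss_df[tss_df.is_accessible]
    report["accessible_tss"] = {
        "n_tss": len(tss_df),
        "n_accessible": int(tss_df.is_accessible.sum()),
        "n_accessible_cgi": int((acc.is_cgi).sum()),
        "by_class": acc.gene_class.value_counts().sort_index().to_dict(),
    }
    enhancers = call_enhancers(
        atac, polII, tss_points,
        cfg.atac_enh_threshold, cfg.polII_enh_threshold, cfg.enh_tss_dist,
    )
    enh_df = pd.DataFrame(
        [
            dict(chrom=e.interval.chrom, start=e.interval.start, end=e.interval.end,
                 midpoint=e.midpoint, mean_atac=e.mean_atac, mean_polII=e.mean_polII,
                 tss_distance=e.tss_distance)
            for e in enhancers
        ]
    )
    enh_df.to_csv(outdir / "enhancers.tsv", sep="\t", index=False)
    cio.write_bed([e.interval for e in enhancers], outdir / "enhancers.bed",
                  scores=[f"{e.mean_atac:.3f}" for e in enhancers])
    report["enhancers"] = {"n_calls": len(enhancers)}

    # stage 6: peak colocalisation and enhancer overrepresentation ---------
    venn_marks = multi_venn(
        {k: peaks[k] for k in ("CFP1", "H3K4me3", "H3K27me3")}, cfg.coloc_gap
    )
    cfp1_k4 = colocalise(peaks["CFP1"], peaks["H3K4me3"], cfg.coloc_gap)
    cfp1_k27 = colocalise(peaks["CFP1"], peaks["H3K27me3"], cfg.coloc_gap)
    intergenic_cfp1 = [
        pk for pk in peaks["CFP1"]
        if classify_summit(pk.interval.chrom, pk.summit, tss_index, gene_index,
                           cgi_index, cfg.tss_near_dist, cfg.tss_cgi_dist).value
        in ("intergenic", "CGI_intergenic")
    ]
    enh_ivs = [e.interval for e in enhancers]
    k_coloc = colocalise(intergenic_cfp1, enh_ivs, cfg.coloc_gap).n_a_hit
    if enh_ivs and intergenic_cfp1:
        over = overrepresentation(k_coloc, len(intergenic_cfp1), enh_ivs, genome)
        over_dict = dict(k=over.k, n=over.n, genome_fraction=over.f,
                         fold=over.fold, log10_p=over.log10_p)
    else:
        over_dict = dict(k=0, n=len(intergenic_cfp1), genome_fraction=0.0,
                         fold=float("nan"), log10_p=0.0)
    report["colocalisation"] = {
        "venn_marks": venn_marks.to_json_dict(),
        "cfp1_with_h3k4me3": cfp1_k4.n_a_hit,
        "cfp1_with_h3k27me3": cfp1_k27.n_a_hit,
        "enhancer_overrepresentation": over_dict,
    }

    # stage 7: CFP1 / H3K27me3 mutual exclusivity at TSSs ------------------
    quad = mutual_exclusivity(tracks["CFP1"], tracks["H3K27me3"], tss_points,
                              width=cfg.window)
    report["mutual_exclusivity"] = {
        "threshold_cfp1": quad.threshold_a,
        "threshold_h3k27me3": quad.threshold_b,
        "n_both": quad.n_both, "n_cfp1_only": quad.n_a_only,
        "n_h3k27me3_only": quad.n_b_only, "n_neither": quad.n_neither,
        "odds_ratio": quad.odds_ratio,
    }

    # stage 8: high-confidence TrxG co-occupancy and allocation ------------
    subunit_names = ["CFP1", "SET1A", "HCF1", "RBBP5", "Menin", "UTX"]
    subunit_peaks = {n: peaks[n] for n in subunit_names}
    hc_regions = high_confidence_regions(subunit_peaks, cfg.top_percentile)
    hc_index = IntervalIndex(hc_regions)
    in_hc = {
        n: [pk for pk in ps
            if hc_index.distance(pk.interval.chrom, pk.summit) == 0]
        for n, ps in subunit_peaks.items()
    }
    venn_set1a = multi_venn(
        {n: in_hc[n] for n in ("CFP1", "SET1A", "HCF1", "RBBP5")}, cfg.coloc_gap
    )
    venn_complexes = multi_venn(
        {n: in_hc[n] for n in ("CFP1", "SET1A", "Menin", "UTX", "RBBP5", "HCF1")},
        cfg.coloc_gap,
    )
    cfp1_set1a = [
        comp.interval
        for comp in multi_venn({"CFP1": in_hc["CFP1"], "SET1A": in_hc["SET1A"]},
                               cfg.coloc_gap).components
        if comp.label == frozenset({"CFP1", "SET1A"})
    ]
    allocation = {}
    for rep_name, rep_regions in (
        ("CFP1-SET1A", cfp1_set1a),
        ("Menin", [pk.interval for pk in in_hc["Menin"]]),
        ("UTX", [pk.interval for pk in in_hc["UTX"]]),
    ):
        if not rep_regions:
            continue
        alloc = allocate_complexes(rep_regions, records, enhancers,
                                   cfg.tss_near_dist, cfg.coloc_gap)
        allocation[rep_name] = {
            "counts": alloc.counts,
            "proportions": alloc.proportions,
            "poisson_se": alloc.poisson_se,
        }
    report["trxg"] = {
        "n_high_confidence_regions": len(hc_regions),
        "set1a_complex_venn": venn_set1a.to_json_dict(),
        "all_complex_venn": venn_complexes.to_json_dict(),
        "allocation": allocation,
    }

    # stage 9: locus matrix, correlations, variance decomposition ----------
    matrix = build_locus_matrix(
        tracks, tss_points, [(e.interval.chrom, e.midpoint) for e in enhancers],
        cpg_track=cpg, width=cfg.window,
    )
    matrix["accessibility"] = accessibility_score(matrix["DNase"], matrix["ATAC"])
    matrix.to_csv(outdir / "locus_matrix.tsv", sep="\t", index=False, float_format="%.6g")
    correlations = {}
    for feat in ("CpG_density", "SET1A", "HCF1", "RBBP5", "H3K4me1", "H3K4me3",
                 "accessibility"):
        r, r2 = pearson_r2(matrix[feat], matrix["CFP1"])
        correlations[feat] = {"R": r, "R2": r2}
    top = matrix[select_top_accessible(matrix["accessibility"], cfg.top_percentile)]
    reg = variance_decomposition(top, list(cfg.regression_features), "CFP1")
    report["signal_model"] = {
        "n_loci": len(matrix),
        "n_top_accessible": len(top),
        "correlations_all_loci": correlations,
        "regression": reg.to_json_dict(),
    }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report
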