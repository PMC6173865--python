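"""Readers and writers for the plain-text genomics formats the pipeline
consumes: BED3/6, narrowPeak, chrom.sizes, GTF, bedGraph and FASTA.

BED-family files are 0-based half-open; GTF is converted from its 1-based
inclusive convention on read.  FASTA access goes through pyfaidx.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyfaidx

from .errors import ValidationError
from .genome import GenomeIndex, GenomicInterval, Peak


# ---------------------------------------------------------------- chrom sizes

def read_chrom_sizes(path) -> GenomeIndex:
    items: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split("\t")[:2]
            items.append((name, int(length)))
    return GenomeIndex(tuple(items))


def write_chrom_sizes(genome: GenomeIndex, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chrom_lengths:
            fh.write(f"{name}\t{length}\n")


# ------------------------------------------------------------------------ BED

def read_bed(path) -> list[GenomicInterval]:
    """BED3 or BED6."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) >= 6 else "."
            name = f[3] if len(f) >= 4 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, scores=None) -> None:
    ivs = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            score = 0 if scores is None else scores[i]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


# ----------------------------------------------------------------- narrowPeak

def read_narrowpeak(path) -> list[Peak]:
    """narrowPeak-style BED: col 7 = enrichment (signalValue), col 9 =
    -log10 q-value (FDR), col 10 = summit offset from start (-1 = absent,
    defaulting to the interval midpoint)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]),
                                 f[5] if len(f) >= 6 else ".",
                                 f[3] if len(f) >= 4 else ".")
            enrichment = float(f[6]) if len(f) >= 7 else float(f[4]) if len(f) >= 5 else 0.0
            if len(f) >= 9 and float(f[8]) >= 0:
                fdr = min(1.0, 10.0 ** (-float(f[8])))
            else:
                fdr = 1.0
            offset = int(f[9]) if len(f) >= 10 else -1
            summit = iv.start + offset if offset >= 0 else iv.midpoint
            peaks.append(Peak(iv, summit, enrichment, fdr))
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            q = -math.log10(p.fdr) if p.fdr > 0 else 300.0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t0\t.\t"
                f"{p.enrichment:.6g}\t-1\t{q:.6g}\t{p.summit - iv.start}\n"
            )


# ------------------------------------------------------------------------ GTF

def read_gtf(path) -> pd.DataFrame:
    """Extract per-transcript TSSs and gene bodies from 'transcript'
    features (or 'gene' features when no transcripts are annotated).

    Returns a DataFrame with columns gene_id, transcript_id, chrom, start,
    end, strand, tss — coordinates converted to 0-based half-open, TSS
    strand-aware (start for '+', end-1 for '-')."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] not in ("transcript", "gene"):
                continue
            attrs = {}
            for item in f[8].strip().strip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                k, _, v = item.partition(" ")
                attrs[k] = v.strip().strip('"')
            start = int(f[3]) - 1
            end = int(f[4])
            strand = f[6]
            rows.append(
                dict(
                    feature=f[2],
                    gene_id=attrs.get("gene_id", "."),
                    transcript_id=attrs.get("transcript_id", attrs.get("gene_id", ".")),
                    chrom=f[0],
                    start=start,
                    end=end,
                    strand=strand,
                    tss=start if strand == "+" else end - 1,
                )
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError(f"no gene/transcript features in {path}")
    if (df["feature"] == "transcript").any():
        df = df[df["feature"] == "transcript"]
    return df.drop(columns="feature").reset_index(drop=True)


def write_gtf(genes: pd.DataFrame, path, source: str = "cpgscape") -> None:
    """Inverse of read_gtf for generated annotation: one gene + one
    transcript line per row (columns chrom, start, end, strand, gene_id)."""
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            base = f"{g.chrom}\t{source}"
            coords = f"{g.start + 1}\t{g.end}\t.\t{g.strand}\t."
            fh.write(f'{base}\tgene\t{coords}\tgene_id "{g.gene_id}";\n')
            fh.write(
                f'{base}\ttranscript\t{coords}\t'
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";\n'
            )


# ---------------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_fasta(path) -> pyfaidx.Fasta:
    return pyfaidx.Fasta(str(path))


# ------------------------------------------------------------------- bedGraph

def write_bedgraph(track, path) -> None:
    """4-column bedGraph, one record per bin, adjacent equal values merged."""
    with open(path, "w") as fh:
        for chrom in track.genome.chroms:
            vals = track.data[chrom]
            length = track.genome.length(chrom)
            bs = track.bin_size
            run_start = 0
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != vals[run_start]:
                    end = min(i * bs, length)
                    fh.write(f"{chrom}\t{run_start * bs}\t{end}\t{vals[run_start]:.6f}\n")
                    run_start = i


def read_bedgraph(path, genome: GenomeIndex, bin_size: int):
    """Read a bedGraph onto a fixed bin grid; values falling across bin
    boundaries are re-binned by length-weighted averaging, bases without a
    record count as 0."""
    from .tracks import CoverageTrack

    track = CoverageTrack.zeros(genome, bin_size)
    weight = {c: np.zeros_like(track.data[c]) for c in genome.chroms}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.rstrip("\n").split("\t")[:4]
            if chrom not in genome:
                raise ValidationError(f"bedGraph chromosome {chrom!r} not in genome")
            s_i, e_i, val = int(s), int(e), float(v)
            arr, w = track.data[chrom], weight[chrom]
            b0, b1 = s_i // bin_size, (e_i - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(s_i, b * bin_size)
                hi = min(e_i, (b + 1) * bin_size)
                arr[b] += val * (hi - lo)
                w[b] += hi - lo
    for c in genome.chroms:
        nz = weight[c] > 0
        track.data[c][nz] /= weight[c][nz]
    return track
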