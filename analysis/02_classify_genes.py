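#!/usr/bin/env python
"""Classify genes as housekeeping / tissue-specific from the 16-tissue
RPKM panel, and report the class counts with their supporting statistics.

Reads the simulated expression matrices from scratch/sim/ (run
01_simulate_epigenome.py first) and writes results/gene_classes.tsv.
"""

from pathlib import Path

import pandas as pd

from cpgscape.classify import gene_classes, housekeeping_stats, tissue_specific_stats

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"


def main() -> None:
    expr16 = pd.read_csv(SIM / "rpkm_16tissues.tsv", sep="\t", index_col=0)
    cells = {
        cell: pd.read_csv(SIM / f"rpkm_{cell}.tsv", sep="\t", index_col=0).mean(axis=1)
        for cell in ("ery", "lym")
    }
    labels = gene_classes(expr16, cells)
    hk = housekeeping_stats(expr16)
    out = hk[["min_rpkm", "sd_log2", "max_abs_log2_ratio"]].copy()
    for cell, ce in cells.items():
        ts = tissue_specific_stats(expr16, ce)
        out[f"{cell}_rpkm"] = ts.cell_rpkm
    out.insert(0, "gene_class", labels)
    (ROOT / "results").mkdir(exist_ok=True)
    out.to_csv(ROOT / "results" / "gene_classes.tsv", sep="\t", float_format="%.4g")
    print(labels.value_counts().to_string())
    print(f"\nwrote {ROOT / 'results' / 'gene_classes.tsv'}")


if __name__ == "__main__":
    main()
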