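#!/usr/bin/env python
"""Generate the synthetic epigenome used by every downstream analysis.

Writes the full dataset (FASTA, annotation, coverage tracks, peak sets,
RPKM panels, truth JSON) under scratch/sim/ and a small summary under
results/.
"""

import json
from pathlib import Path

from cpgscape.simulate import SimConfig, simulate_all, write_simulation

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    cfg = SimConfig()
    sim, track_sims, expr = simulate_all(cfg, SEED)
    outdir = ROOT / "scratch" / "sim"
    write_simulation(outdir, sim, track_sims, expr)

    summary = {
        "seed": SEED,
        "genome_bp": sim.genome.total_length,
        "n_genes": len(sim.genes),
        "n_cgis": len(sim.cgis),
        "n_enhancer_sites": len(sim.enhancer_sites),
        "gene_classes": sim.genes.gene_class.value_counts().to_dict(),
        "cgi_promoters": int(sim.genes.has_cgi.sum()),
    }
    (ROOT / "results").mkdir(exist_ok=True)
    with open(ROOT / "results" / "simulation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(f"wrote synthetic epigenome to {outdir}")
    print(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
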