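#!/usr/bin/env python
"""Peak co-occupancy analyses: CFP1 association with chromatin marks,
enhancer overrepresentation of intergenic CFP1 peaks, CFP1/H3K27me3
mutual exclusivity, and TrxG-subunit colocalisation in high-confidence
regions.

These are the statistics the full pipeline computes in stages 6-8; this
driver runs them standalone and writes results/cooccupancy.json.
"""

import json
from pathlib import Path

from cpgscape.pipeline import AnalysisConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    report = run_pipeline(ROOT / "scratch" / "sim", ROOT / "scratch" / "pipeline_out",
                          AnalysisConfig())
    keep = {
        k: report[k]
        for k in ("colocalisation", "mutual_exclusivity", "trxg", "summits")
    }
    (ROOT / "results").mkdir(exist_ok=True)
    with open(ROOT / "results" / "cooccupancy.json", "w") as fh:
        json.dump(keep, fh, indent=1, sort_keys=True)
    over = keep["colocalisation"]["enhancer_overrepresentation"]
    print(f"intergenic CFP1 peaks colocalised with enhancers: {over['k']}/{over['n']} "
          f"({over['fold']:.0f}-fold, log10 p = {over['log10_p']:.1f})")
    me = keep["mutual_exclusivity"]
    print(f"CFP1/H3K27me3 quadrants both={me['n_both']} cfp1={me['n_cfp1_only']} "
          f"k27={me['n_h3k27me3_only']} neither={me['n_neither']} "
          f"OR={me['odds_ratio']:.3f}")
    print(f"wrote {ROOT / 'results' / 'cooccupancy.json'}")


if __name__ == "__main__":
    main()
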