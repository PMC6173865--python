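#!/usr/bin/env python
"""Call accessible TSSs (ATAC > 10 within 1 kb) and putative enhancers
(ATAC > 10 and Pol II > 5, more than 2 kb from every TSS) on the
normalised, input-subtracted erythroid-style tracks.

Writes results/enhancers.tsv and prints the accessible-TSS breakdown.
"""

from pathlib import Path

import pandas as pd

from cpgscape import io as cio
from cpgscape.features import call_accessible_tss, call_enhancers
from cpgscape.tracks import normalize_1x, subtract_input

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"


def main() -> None:
    genome = cio.read_chrom_sizes(SIM / "genome.chrom.sizes")
    genes = cio.read_gtf(SIM / "genes.gtf")
    inp = normalize_1x(cio.read_bedgraph(SIM / "ery" / "input.bedgraph", genome, 50))
    atac = subtract_input(
        normalize_1x(cio.read_bedgraph(SIM / "ery" / "ATAC.bedgraph", genome, 50)), inp
    )
    polII = subtract_input(
        normalize_1x(cio.read_bedgraph(SIM / "ery" / "PolII.bedgraph", genome, 50)), inp
    )
    tss = [(g.chrom, g.tss) for g in genes.itertuples()]

    accessible = [call_accessible_tss(atac, c, p) for c, p in tss]
    print(f"accessible TSSs: {sum(accessible)} / {len(tss)}")

    calls = call_enhancers(atac, polII, tss)
    df = pd.DataFrame(
        [
            dict(chrom=c.interval.chrom, start=c.interval.start, end=c.interval.end,
                 midpoint=c.midpoint, mean_atac=round(c.mean_atac, 3),
                 mean_polII=round(c.mean_polII, 3), tss_distance=c.tss_distance)
            for c in calls
        ]
    )
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "enhancers.tsv", sep="\t", index=False)
    print(f"putative enhancers: {len(calls)} "
          f"(min TSS distance {df.tss_distance.min():.0f} bp)")
    print(f"wrote {ROOT / 'results' / 'enhancers.tsv'}")


if __name__ == "__main__":
    main()
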