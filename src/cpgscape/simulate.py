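"""Seed-deterministic synthetic epigenome with planted ground truth.

The generator emulates the statistical structure the downstream pipeline
is built to measure, at desk scale (2 Mb over two chromosomes):

* a background sequence with ~1% CpG dinucleotide starts and planted
  high-CpG islands (500–1500 bp, >= 10% CpG starts);
* genes whose promoters are half CGI-associated (< 1 kb) and half not,
  with planted housekeeping / tissue-specific / silent-Polycomb / filler
  classes and a matching 16-pseudo-tissue RPKM panel;
* putative enhancers (high ATAC + Pol II) placed well clear of every TSS,
  partly cell-type-specific and partly shared between the two cell types;
* binned coverage tracks in which CFP1 is a planted linear function of
  CpG density, H3K4me3 and SET1A plus noise, H3K27me3 marks only silent
  Polycomb promoters (mutual exclusivity with CFP1), and H3K4me1 is
  bimodal around enhancers;
* narrowPeak files for six TrxG subunits with a planted co-occupancy
  pattern.

Tracks are emitted raw (half-normal background noise keeps coverage
non-negative); the pipeline's own 1x normalisation and input subtraction
rescale them, so the truth records the *effective* linear coefficients on
the normalised scale alongside the nominal generating ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome import GenomeIndex, GenomicInterval, Peak
from .tracks import CoverageTrack, cpg_density_track, window_mean
from . import io as cio

TRACK_NAMES = [
    "CFP1", "SET1A", "HCF1", "RBBP5", "Menin", "UTX",
    "H3K4me3", "H3K4me1", "H3K27me3", "ATAC", "DNase", "PolII", "input",
]
SUBUNITS = ["CFP1", "SET1A", "HCF1", "RBBP5", "Menin", "UTX"]
GENE_CLASSES = ["housekeeping", "ts_ery", "ts_lym", "silent_pcg", "filler"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic epigenome."""

    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 1_000_000), ("chr2", 1_000_000))
    bin_size: int = 50
    # gene classes (sum = n_genes)
    n_housekeeping: int = 60
    n_ts_ery: int = 20
    n_ts_lym: int = 20
    n_silent_pcg: int = 50
    n_filler: int = 50
    n_extra_cgis: int = 12
    n_other_sites: int = 10          # intergenic TrxG-only regulatory sites
    n_enhancers_specific: int = 15   # per cell type
    n_enhancers_shared: int = 5
    # sequence composition
    background_cg_keep: float = 0.25  # thinning of iid CG starts -> ~1%
    cgi_cg_token_prob: float = 0.15   # token scheme -> ~13% CG starts
    cgi_length: tuple[int, int] = (500, 1500)
    gene_length: tuple[int, int] = (2000, 6000)
    # bump shapes (bp)
    tss_mark_sd: float = 150.0
    enhancer_mark_sd: float = 200.0
    k27me3_sd: float = 400.0
    k4me1_offset: float = 500.0
    # amplitude ranges on the raw scale
    atac_tss_amp: tuple[float, float] = (30.0, 80.0)
    atac_enh_amp: tuple[float, float] = (30.0, 50.0)
    dnase_factor: tuple[float, float] = (0.8, 1.2)
    pol2_tss_amp: tuple[float, float] = (5.0, 30.0)
    pol2_enh_amp: tuple[float, float] = (15.0, 25.0)
    k4me3_amp: tuple[float, float] = (5.0, 40.0)
    k4me1_amp: tuple[float, float] = (5.0, 20.0)
    k27me3_amp: tuple[float, float] = (10.0, 30.0)
    subunit_amp: tuple[float, float] = (5.0, 40.0)
    # planted linear model: CFP1 = baseline + a·CpG% + b·H3K4me3 + c·SET1A + ε
    coef_cpg: float = 0.5
    coef_k4me3: float = 0.6
    coef_set1a: float = 0.8
    cfp1_baseline: float = 6.0
    cfp1_locus_noise_sd: float = 2.5
    # background noise
    noise_sd: float = 1.0
    input_noise_sd: float = 0.1
    expression_tissues: int = 16
    samples_per_cell: int = 3

    @property
    def n_genes(self) -> int:
        return (self.n_housekeeping + self.n_ts_ery + self.n_ts_lym
                + self.n_silent_pcg + self.n_filler)

    @property
    def genome(self) -> GenomeIndex:
        return GenomeIndex(tuple(self.chrom_lengths))


# ------------------------------------------------------------------ genome

# membership probabilities per (site type, subunit); SET1A/HCF1/RBBP5 are
# drawn conditionally to plant the SET1A-complex co-occupancy structure
CFP1_P = {"aCGI": 0.97, "aNCG": 0.6, "ENH": 0.5, "SIL": 0.0, "OTH": 0.2}
MENIN_P = {"aCGI": 0.6, "aNCG": 0.3, "ENH": 0.2, "SIL": 0.2, "OTH": 0.4}
UTX_P = {"aCGI": 0.3, "aNCG": 0.2, "ENH": 0.7, "SIL": 0.3, "OTH": 0.5}
SET1A_GIVEN_CFP1, SET1A_GIVEN_NOT = 0.85, 0.03
HCF1_GIVEN_SET1A_CFP1, HCF1_GIVEN_MENIN, HCF1_BASE = 0.85, 0.4, 0.02
RBBP5_GIVEN_ANY, RBBP5_BASE = 0.92, 0.03


@dataclass
class SimGenome:
    config: SimConfig
    genome: GenomeIndex
    sequences: dict[str, str]
    genes: pd.DataFrame          # gene_id, chrom, start, end, strand, tss, gene_class, has_cgi, active_ery, active_lym
    cgis: list[GenomicInterval]
    enhancer_sites: pd.DataFrame  # site_id, chrom, pos, in_ery, in_lym
    other_sites: pd.DataFrame     # site_id, chrom, pos

    def tss_points(self) -> list[tuple[str, int]]:
        return list(zip(self.genes.chrom, self.genes.tss))


def _island_sequence(rng: np.random.Generator, length: int, p_cg: float) -> str:
    parts: list[str] = []
    n = 0
    alphabet = np.array(["CG", "A", "C", "G", "T"])
    probs = [p_cg] + [(1 - p_cg) / 4] * 4
    while n < length:
        draw = rng.choice(alphabet, size=length, p=probs)
        chunk = "".join(draw)
        parts.append(chunk)
        n += len(chunk)
    return "".join(parts)[:length]


def _cg_start_fraction(seq: str) -> float:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return float(((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).mean())


def _background_sequence(rng: np.random.Generator, length: int, cg_keep: float) -> np.ndarray:
    bases = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)
    seq = rng.choice(bases, size=length, p=[0.3, 0.2, 0.2, 0.3])
    cg = np.nonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))[0]
    drop = cg[rng.random(len(cg)) > cg_keep]
    seq[drop + 1] = rng.choice(np.array([ord("A"), ord("T")], dtype=np.uint8), size=len(drop))
    return seq


def simulate_genome(config: SimConfig, seed: int) -> SimGenome:
    """Place genes, CGIs, enhancers and other regulatory sites on a slot
    grid and synthesise the sequence.  Deterministic given (config, seed)."""
    rng = np.random.default_rng(seed)
    genome = config.genome
    n_enh = 2 * config.n_enhancers_specific + config.n_enhancers_shared
    slots_needed = config.n_genes + config.n_extra_cgis + config.n_other_sites + n_enh

    # distribute slots across chromosomes proportionally to length
    chroms = genome.chroms
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    per_chrom = np.floor(slots_needed * lengths / lengths.sum()).astype(int)
    while per_chrom.sum() < slots_needed:
        per_chrom[np.argmax(lengths / (per_chrom + 1))] += 1
    slot_sizes = lengths / per_chrom
    if (slot_sizes < 7000).any():
        raise ValidationError("too many features for genome size (slots < 7 kb)")

    kinds = (["gene"] * config.n_genes + ["cgi"] * config.n_extra_cgis
             + ["other"] * config.n_other_sites + ["enh"] * n_enh)
    kinds = list(np.array(kinds)[rng.permutation(len(kinds))])
    positions: list[tuple[str, int]] = []
    k = 0
    for c, n_slot in zip(chroms, per_chrom):
        size = genome.length(c) / n_slot
        for s in range(int(n_slot)):
            center = int((s + 0.5) * size) + int(rng.integers(-500, 501))
            positions.append((c, center))
            k += 1
    slot_df = pd.DataFrame(
        {"chrom": [c for c, _ in positions], "pos": [p for _, p in positions], "kind": kinds}
    )

    # gene table
    gene_rows = []
    classes = ([GENE_CLASSES[0]] * config.n_housekeeping
               + [GENE_CLASSES[1]] * config.n_ts_ery
               + [GENE_CLASSES[2]] * config.n_ts_lym
               + [GENE_CLASSES[3]] * config.n_silent_pcg
               + [GENE_CLASSES[4]] * config.n_filler)
    classes = list(np.array(classes)[rng.permutation(len(classes))])
    class_counter: dict[str, int] = {}
    gene_slots = slot_df[slot_df.kind == "gene"].reset_index(drop=True)
    for i, row in gene_slots.iterrows():
        cls = classes[i]
        j = class_counter.get(cls, 0)
        class_counter[cls] = j + 1
        has_cgi = (j % 2 == 0)  # half of each class gets a promoter CGI
        length = int(rng.integers(*config.gene_length))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(row.pos)
        if strand == "+":
            start, end = tss, min(tss + length, config.genome.length(row.chrom))
        else:
            start, end = max(tss - length + 1, 0), tss + 1
        filler_active_ery = cls == "filler" and (j % 2 == 0)
        gene_rows.append(
            dict(
                gene_id=f"g{i:04d}", chrom=row.chrom, start=start, end=end,
                strand=strand, tss=tss, gene_class=cls, has_cgi=has_cgi,
                active_ery=cls in ("housekeeping", "ts_ery") or filler_active_ery,
                active_lym=cls in ("housekeeping", "ts_lym")
                or (cls == "filler" and not filler_active_ery),
            )
        )
    genes = pd.DataFrame(gene_rows)

    # CGIs: one per CGI-flagged promoter plus intergenic extras
    cgis: list[GenomicInterval] = []
    for _, g in genes[genes.has_cgi].iterrows():
        L = int(rng.integers(*config.cgi_length))
        offset = int(rng.integers(100, L - 100))
        start = max(g.tss - offset, 0)
        cgis.append(GenomicInterval(g.chrom, start, start + L, name=f"cgi_{g.gene_id}"))
    for i, (_, row) in enumerate(slot_df[slot_df.kind == "cgi"].iterrows()):
        L = int(rng.integers(*config.cgi_length))
        start = max(int(row.pos) - L // 2, 0)
        cgis.append(GenomicInterval(row.chrom, start, start + L, name=f"cgi_extra{i:02d}"))

    # enhancer and other-site tables
    enh_slots = slot_df[slot_df.kind == "enh"].reset_index(drop=True)
    ns, nsh = config.n_enhancers_specific, config.n_enhancers_shared
    enh_rows = []
    for i, row in enh_slots.iterrows():
        in_ery = i < ns or i >= 2 * ns
        in_lym = ns <= i
        enh_rows.append(dict(site_id=f"enh{i:03d}", chrom=row.chrom, pos=int(row.pos),
                             in_ery=in_ery, in_lym=in_lym))
    enhancer_sites = pd.DataFrame(enh_rows)
    other_sites = pd.DataFrame(
        [dict(site_id=f"oth{i:03d}", chrom=r.chrom, pos=int(r.pos))
         for i, (_, r) in enumerate(slot_df[slot_df.kind == "other"].iterrows())]
    )

    # sequence: background with CpG thinning, islands pasted over CGI spans
    sequences: dict[str, str] = {}
    arrays = {
        c: _background_sequence(rng, genome.length(c), config.background_cg_keep)
        for c in chroms
    }
    for iv in cgis:
        for _ in range(20):
            island = _island_sequence(rng, iv.length, config.cgi_cg_token_prob)
            if _cg_start_fraction(island) >= 0.105:
                break
        arrays[iv.chrom][iv.start : iv.end] = np.frombuffer(island.encode(), dtype=np.uint8)
    for c in chroms:
        sequences[c] = arrays[c].tobytes().decode("ascii")

    return SimGenome(config, genome, sequences, genes, cgis, enhancer_sites, other_sites)


# ------------------------------------------------------------------- tracks

def _add_bump(arr: np.ndarray, bin_size: int, center: float, amp: float, sd: float) -> None:
    n = len(arr)
    i0 = max(int((center - 4 * sd) // bin_size), 0)
    i1 = min(int((center + 4 * sd) // bin_size) + 1, n)
    if i0 >= i1:
        return
    mids = np.arange(i0, i1) * bin_size + bin_size / 2.0
    arr[i0:i1] += amp * np.exp(-((mids - center) ** 2) / (2.0 * sd * sd))


@dataclass
class TrackTruth:
    cell: str
    coef_nominal: dict[str, float]
    coef_effective: dict[str, float]
    track_means: dict[str, float]
    loci: pd.DataFrame  # locus_id, chrom, pos, kind, systematic CFP1 window mean, noise sd
    membership: pd.DataFrame
    site_table: pd.DataFrame


@dataclass
class TrackSim:
    cell: str
    tracks: dict[str, CoverageTrack]
    peaks: dict[str, list[Peak]]
    truth: TrackTruth


def _uniform(rng, lo_hi) -> float:
    return float(rng.uniform(*lo_hi))


def simulate_tracks(sim: SimGenome, seed: int, cell: str = "ery") -> TrackSim:
    """Build the thirteen raw coverage tracks and the subunit peak sets for
    one cell type."""
    if cell not in ("ery", "lym"):
        raise ValidationError("cell must be 'ery' or 'lym'")
    cfg = sim.config
    rng = np.random.default_rng(seed)
    genome, bs = sim.genome, cfg.bin_size

    site_rows = []
    for _, g in sim.genes.iterrows():
        if g[f"active_{cell}"]:
            stype = "aCGI" if g.has_cgi else "aNCG"
        elif g.gene_class == "silent_pcg":
            stype = "SIL"
        else:
            stype = "inactive"
        site_rows.append(dict(site_id=g.gene_id, chrom=g.chrom, pos=g.tss, site_type=stype))
    enh_mask = sim.enhancer_sites[f"in_{cell}"]
    for _, e in sim.enhancer_sites[enh_mask].iterrows():
        site_rows.append(dict(site_id=e.site_id, chrom=e.chrom, pos=e.pos, site_type="ENH"))
    for _, o in sim.other_sites.iterrows():
        site_rows.append(dict(site_id=o.site_id, chrom=o.chrom, pos=o.pos, site_type="OTH"))
    sites = pd.DataFrame(site_rows)

    # subunit membership with planted SET1A-complex conditional structure
    n = len(sites)
    u = {s: rng.random(n) for s in ["CFP1", "SET1A", "HCF1", "RBBP5", "Menin", "UTX"]}
    stype = sites.site_type.to_numpy()
    def p_by_type(table):
        return np.array([table.get(t, 0.0) for t in stype])
    memb = pd.DataFrame(index=sites.site_id)
    memb["CFP1"] = u["CFP1"] < p_by_type(CFP1_P)
    p_set = np.where(memb["CFP1"], SET1A_GIVEN_CFP1, SET1A_GIVEN_NOT)
    p_set = np.where(stype == "SIL", 0.0, p_set)
    p_set = np.where(stype == "inactive", 0.0, p_set)
    memb["SET1A"] = u["SET1A"] < p_set
    memb["Menin"] = u["Menin"] < p_by_type(MENIN_P)
    memb["UTX"] = u["UTX"] < p_by_type(UTX_P)
    p_hcf = np.where(memb["CFP1"] & memb["SET1A"], HCF1_GIVEN_SET1A_CFP1,
                     np.where(memb["Menin"], HCF1_GIVEN_MENIN, HCF1_BASE))
    memb["HCF1"] = u["HCF1"] < p_hcf
    any_trxg = memb[["CFP1", "SET1A", "Menin", "UTX"]].any(axis=1).to_numpy()
    memb["RBBP5"] = u["RBBP5"] < np.where(any_trxg, RBBP5_GIVEN_ANY, RBBP5_BASE)
    memb.loc[stype == "inactive", :] = False

    # amplitudes
    amp = pd.DataFrame(0.0, index=sites.site_id, columns=TRACK_NAMES[:-1])
    is_tss_active = np.isin(stype, ["aCGI", "aNCG"])
    is_enh = stype == "ENH"
    is_sil = stype == "SIL"
    for sub in SUBUNITS:
        if sub == "CFP1":
            continue  # CFP1 is the planted linear response, not a free amplitude
        amp.loc[memb[sub].to_numpy(), sub] = rng.uniform(
            *cfg.subunit_amp, size=int(memb[sub].sum())
        )
    amp.loc[is_tss_active, "H3K4me3"] = rng.uniform(*cfg.k4me3_amp, size=int(is_tss_active.sum()))
    amp.loc[is_enh, "H3K4me1"] = rng.uniform(*cfg.k4me1_amp, size=int(is_enh.sum()))
    amp.loc[is_sil, "H3K27me3"] = rng.uniform(*cfg.k27me3_amp, size=int(is_sil.sum()))
    amp.loc[is_tss_active, "ATAC"] = rng.uniform(*cfg.atac_tss_amp, size=int(is_tss_active.sum()))
    amp.loc[is_enh, "ATAC"] = rng.uniform(*cfg.atac_enh_amp, size=int(is_enh.sum()))
    amp.loc[:, "DNase"] = amp["ATAC"] * rng.uniform(*cfg.dnase_factor, size=n)
    amp.loc[is_tss_active, "PolII"] = rng.uniform(*cfg.pol2_tss_amp, size=int(is_tss_active.sum()))
    amp.loc[is_enh, "PolII"] = rng.uniform(*cfg.pol2_enh_amp, size=int(is_enh.sum()))

    # noiseless signal fields D per track
    D = {t: CoverageTrack.zeros(genome, bs) for t in TRACK_NAMES if t != "input"}
    cpg = cpg_density_track(sim.sequences, genome, bs)
    for i, s in sites.reset_index(drop=True).iterrows():
        sd = cfg.enhancer_mark_sd if s.site_type == "ENH" else cfg.tss_mark_sd
        for t in ["SET1A", "HCF1", "RBBP5", "Menin", "UTX", "H3K4me3", "ATAC", "DNase", "PolII"]:
            a = amp.iloc[i][t]
            if a > 0:
                _add_bump(D[t].data[s.chrom], bs, s.pos, a, sd)
        if amp.iloc[i]["H3K27me3"] > 0:
            _add_bump(D["H3K27me3"].data[s.chrom], bs, s.pos, amp.iloc[i]["H3K27me3"], cfg.k27me3_sd)
        if amp.iloc[i]["H3K4me1"] > 0:
            for off in (-cfg.k4me1_offset, cfg.k4me1_offset):
                _add_bump(D["H3K4me1"].data[s.chrom], bs, s.pos + off, amp.iloc[i]["H3K4me1"], cfg.enhancer_mark_sd)

    # CFP1 planted linear model (baseline + a·CpG% + b·K4me3 + c·SET1A),
    # plus a per-locus amplitude noise bump at active TSSs and enhancers
    eps = {}
    for c in genome.chroms:
        D["CFP1"].data[c] = (
            cfg.cfp1_baseline
            + cfg.coef_cpg * cpg.data[c]
            + cfg.coef_k4me3 * D["H3K4me3"].data[c]
            + cfg.coef_set1a * D["SET1A"].data[c]
        )
    noisy_sites = sites[np.isin(stype, ["aCGI", "aNCG", "ENH"])]
    for _, s in noisy_sites.iterrows():
        e = float(rng.normal(0.0, cfg.cfp1_locus_noise_sd))
        eps[s.site_id] = e
        sd = cfg.enhancer_mark_sd if s.site_type == "ENH" else cfg.tss_mark_sd
        _add_bump(D["CFP1"].data[s.chrom], bs, s.pos, e, sd)

    # raw tracks: planted field + half-normal background noise; the input
    # is flat 1x plus noise so subtraction is non-trivial
    tracks: dict[str, CoverageTrack] = {}
    for t in TRACK_NAMES:
        data = {}
        for c in genome.chroms:
            nb = genome.n_bins(c, bs)
            if t == "input":
                data[c] = 1.0 + np.abs(rng.normal(0.0, cfg.input_noise_sd, nb))
            else:
                data[c] = np.maximum(D[t].data[c] + np.abs(rng.normal(0.0, cfg.noise_sd, nb)), 0.0)
        tracks[t] = CoverageTrack(genome, bs, data)

    means = {t: tracks[t].global_mean() for t in TRACK_NAMES}
    m_c, m_k, m_s = means["CFP1"], means["H3K4me3"], means["SET1A"]
    coef_eff = {
        "CpG_density": cfg.coef_cpg / m_c,
        "H3K4me3": cfg.coef_k4me3 * m_k / m_c,
        "SET1A": cfg.coef_set1a * m_s / m_c,
    }

    # per-locus systematic CFP1 window means on the normalised scale
    loci_rows = []
    for _, s in sites.iterrows():
        if s.site_type == "OTH":
            continue
        kind = "enhancer" if s.site_type == "ENH" else "TSS"
        sd = cfg.enhancer_mark_sd if s.site_type == "ENH" else cfg.tss_mark_sd
        # window-mean shape factor of a unit bump at this locus
        probe = np.zeros(genome.n_bins(s.chrom, bs))
        _add_bump(probe, bs, s.pos, 1.0, sd)
        g_i = window_mean(CoverageTrack(genome, bs, {c: probe if c == s.chrom else
                                                     np.zeros(genome.n_bins(c, bs))
                                                     for c in genome.chroms}), s.chrom, s.pos)
        sys_raw = window_mean(D["CFP1"], s.chrom, s.pos) - eps.get(s.site_id, 0.0) * g_i
        loci_rows.append(
            dict(
                locus_id=s.site_id, chrom=s.chrom, pos=s.pos, kind=kind,
                site_type=s.site_type,
                cfp1_systematic=sys_raw / m_c - 1.0,
                noise_sd=cfg.cfp1_locus_noise_sd * g_i / m_c,
            )
        )
    loci = pd.DataFrame(loci_rows)

    # peak files: subunits at member sites, K4me3 at active TSSs, K27me3
    # (broad) at silent Polycomb TSSs
    peaks: dict[str, list[Peak]] = {t: [] for t in SUBUNITS + ["H3K4me3", "H3K27me3"]}
    half = {"narrow": 250, "broad": 600}
    for i, s in sites.reset_index(drop=True).iterrows():
        for sub in SUBUNITS:
            if memb.iloc[i][sub]:
                enrich = (float(D[sub].data[s.chrom][s.pos // bs]) if sub == "CFP1"
                          else float(amp.iloc[i][sub]))
                iv = GenomicInterval(s.chrom, s.pos - half["narrow"], s.pos + half["narrow"])
                peaks[sub].append(Peak(iv, s.pos, max(enrich, 0.0), float(rng.uniform(0, 0.01))))
        if amp.iloc[i]["H3K4me3"] > 0:
            iv = GenomicInterval(s.chrom, s.pos - half["narrow"], s.pos + half["narrow"])
            peaks["H3K4me3"].append(Peak(iv, s.pos, float(amp.iloc[i]["H3K4me3"]), float(rng.uniform(0, 0.01))))
        if amp.iloc[i]["H3K27me3"] > 0:
            iv = GenomicInterval(s.chrom, s.pos - half["broad"], s.pos + half["broad"])
            peaks["H3K27me3"].append(Peak(iv, s.pos, float(amp.iloc[i]["H3K27me3"]), float(rng.uniform(0, 0.01))))

    truth = TrackTruth(
        cell=cell,
        coef_nominal={"CpG_density": cfg.coef_cpg, "H3K4me3": cfg.coef_k4me3, "SET1A": cfg.coef_set1a},
        coef_effective=coef_eff,
        track_means=means,
        loci=loci,
        membership=memb,
        site_table=sites,
    )
    return TrackSim(cell, tracks, peaks, truth)


# --------------------------------------------------------------- expression

def simulate_expression(sim: SimGenome, seed: int) -> dict:
    """16-pseudo-tissue RPKM panel plus per-cell sample matrices, built so
    that every planted label is recoverable from the emitted values alone
    (each draw is checked against the classification clauses and redrawn
    until it lands in its intended class)."""
    cfg = sim.config
    rng = np.random.default_rng(seed)
    nt = cfg.expression_tissues
    genes = sim.genes

    def hk_ok(v):
        fl = np.maximum(v, 0.1)
        return (v.min() >= 0.1 and np.log2(fl).std(ddof=1) < 1.0
                and np.abs(np.log2(fl / fl.mean())).max() <= 2.0)

    def candidate_ok(v):
        return bool(v.max() <= 0.1 or (v <= 0.1 * v.max()).sum() > nt // 2)

    panel = np.zeros((len(genes), nt))
    cell_val = {"ery": np.zeros(len(genes)), "lym": np.zeros(len(genes))}
    for i, (_, g) in enumerate(genes.iterrows()):
        cls = g.gene_class
        for _ in range(200):
            if cls == "housekeeping":
                base = 2.0 ** rng.uniform(1, 5)
                v = base * 2.0 ** rng.normal(0, 0.3, nt)
                ok = hk_ok(v)
                c_ery = c_lym = base * 2.0 ** float(rng.normal(0, 0.2))
            elif cls in ("ts_ery", "ts_lym"):
                if rng.random() < 0.5:
                    v = rng.uniform(0.001, 0.1, nt)
                else:
                    M = rng.uniform(5, 50)
                    v = np.concatenate([rng.uniform(0.3 * M, M, 5), rng.uniform(0.0, 0.08 * M, nt - 5)])
                    v = v[rng.permutation(nt)]
                ok = candidate_ok(v) and not hk_ok(v)
                hi = float(rng.uniform(0.6, 2.0)) * v.max()
                lo = float(rng.uniform(0.0, 0.2)) * v.max()
                c_ery, c_lym = (hi, lo) if cls == "ts_ery" else (lo, hi)
            elif cls == "silent_pcg":
                v = rng.uniform(0.02, 0.1, nt)
                v[int(rng.integers(nt))] = rng.uniform(0.08, 0.1)
                ok = candidate_ok(v)
                c_ery = c_lym = float(rng.uniform(0.001, 0.008))
            else:  # filler: variable expression, neither housekeeping nor candidate
                v = 2.0 ** rng.normal(rng.uniform(0, 3), 1.3, nt)
                ok = (not hk_ok(v)) and (not candidate_ok(v))
                c = float(rng.uniform(1, 20))
                c_ery = c if g.active_ery else float(rng.uniform(0, 0.1))
                c_lym = c if g.active_lym else float(rng.uniform(0, 0.1))
            if ok:
                break
        else:
            raise ValidationError(f"could not generate class-consistent profile for {g.gene_id}")
        panel[i] = v
        cell_val["ery"][i], cell_val["lym"][i] = c_ery, c_lym

    tissue_df = pd.DataFrame(panel, index=genes.gene_id,
                             columns=[f"T{j + 1:02d}" for j in range(nt)])
    cells = {}
    for cell in ("ery", "lym"):
        for _ in range(200):
            samples = cell_val[cell][:, None] * 2.0 ** rng.normal(
                0, 0.1, (len(genes), cfg.samples_per_cell)
            )
            sample_mean = samples.mean(axis=1)
            # sample noise must not flip any planted tissue-specific call
            is_ts = (genes.gene_class == f"ts_{cell}").to_numpy()
            vmax = panel.max(axis=1)
            is_candidate = np.array([candidate_ok(panel[i]) for i in range(len(genes))])
            flip = (is_ts & (sample_mean < 0.5 * vmax)) | (
                ~is_ts & is_candidate & (sample_mean >= 0.5 * vmax)
            )
            if not flip.any():
                break
        cells[cell] = pd.DataFrame(
            samples, index=genes.gene_id,
            columns=[f"{cell}_s{j + 1}" for j in range(cfg.samples_per_cell)],
        )

    labels = genes.set_index("gene_id").gene_class.map(
        {"housekeeping": "housekeeping", "ts_ery": "tissue_specific(ery)",
         "ts_lym": "tissue_specific(lym)", "silent_pcg": "other", "filler": "other"}
    )
    return {"tissues": tissue_df, "cells": cells, "labels": labels}


# ------------------------------------------------------------------ writing

def write_simulation(outdir, sim: SimGenome, track_sims: dict[str, TrackSim],
                     expr: dict) -> None:
    """Emit every artefact as plain text: FASTA, chrom.sizes, GTF, CGI BED,
    one bedGraph per track, narrowPeak per peak set, RPKM TSVs and a truth
    JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_fasta(sim.sequences, out / "genome.fa")
    cio.write_chrom_sizes(sim.genome, out / "genome.chrom.sizes")
    cio.write_gtf(sim.genes, out / "genes.gtf")
    cio.write_bed(sim.cgis, out / "cgis.bed")
    expr["tissues"].to_csv(out / "rpkm_16tissues.tsv", sep="\t", float_format="%.6g")
    for cell, df in expr["cells"].items():
        df.to_csv(out / f"rpkm_{cell}.tsv", sep="\t", float_format="%.6g")
    truth = {
        "gene_classes": sim.genes.set_index("gene_id").gene_class.to_dict(),
        "gene_labels": expr["labels"].to_dict(),
        "has_cgi": sim.genes.set_index("gene_id").has_cgi.astype(bool).to_dict(),
        "enhancers": sim.enhancer_sites.to_dict(orient="records"),
        "other_sites": sim.other_sites.to_dict(orient="records"),
        "cells": {},
    }
    for cell, ts in track_sims.items():
        d = out / cell
        d.mkdir(exist_ok=True)
        for name, track in ts.tracks.items():
            cio.write_bedgraph(track, d / f"{name}.bedgraph")
        for name, plist in ts.peaks.items():
            cio.write_narrowpeak(plist, d / f"{name}.narrowPeak")
        truth["cells"][cell] = {
            "coef_nominal": ts.truth.coef_nominal,
            "coef_effective": ts.truth.coef_effective,
            "track_means": ts.truth.track_means,
            "loci": ts.truth.loci.to_dict(orient="records"),
            "membership": ts.truth.membership.astype(bool).reset_index().to_dict(orient="records"),
            "site_types": ts.truth.site_table.to_dict(orient="records"),
        }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def simulate_all(config: SimConfig, seed: int, cells=("ery", "lym")) -> tuple:
    """Convenience wrapper: genome + tracks per cell + expression, with
    sub-seeds derived deterministically from the master seed."""
    sim = simulate_genome(config, seed)
    track_sims = {
        cell: simulate_tracks(sim, seed + 1000 * (i + 1), cell)
        for i, cell in enumerate(cells)
    }
    expr = simulate_expression(sim, seed + 7)
    return sim, track_sims, expr
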