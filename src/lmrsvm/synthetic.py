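"""Seeded toy genomes with planted enhancers and all companion tracks.

The generator emulates the inputs of the real pipeline at desk scale: a few
hundred-kb chromosomes of i.i.d. background sequence, planted enhancers whose
sequences are enriched for a small set of motif words (giving them a distinct
5-mer profile, the premise that makes enhancer composition learnable), LMR
calls covering a mix of enhancers and background, a VISTA-like anchor subset,
exons, TSS points, DHS/p300/TF marker peaks placed preferentially on true
enhancers, a FANTOM-style enhancer track and conserved segments.  All
randomness flows from a single seed through one named generator; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome_io import Genome, GenomicInterval, write_bed, write_fasta

__all__ = ["SimConfig", "SimData", "simulate", "write_all"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated genome.

    Defaults: three 400 kb chromosomes at 40% background GC; five planted
    enhancers per chromosome, 1.2-2 kb long — commensurate with the 2 kb
    scan window, as for real enhancers at the scale the window size was
    chosen for, and about 2% of bases, the same order as genome-wide
    enhancer coverage under a 5% prediction cap; four
    hexamer motif words planted at rate 0.5 per 20 bp slot inside enhancers;
    240 LMRs of which half sit on enhancers; 30% of the enhancer-covering
    LMRs anchored by a VISTA-like fragment.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (400_000, 400_000, 400_000)
    gc_background: float = 0.40
    n_gap_length: int = 1000            # one N island per chromosome; 0 disables
    motifs: tuple[str, ...] = ("GGCGCC", "CGGACG", "GCCGTA", "CGCTGG")
    motif_spacing: int = 20
    motif_rate: float = 0.5
    enhancers_per_chrom: int = 5
    enhancer_length: tuple[int, int] = (1200, 2000)
    enhancer_margin: int = 8000         # min gap between enhancers / chrom edges
    lmr_count: int = 240
    lmr_enhancer_fraction: float = 0.5
    lmr_background_length: tuple[int, int] = (300, 1500)
    lmr_jitter: int = 150
    vista_fraction: float = 0.3
    exons_per_chrom: int = 30
    exon_length: tuple[int, int] = (150, 300)
    tss_per_chrom: int = 15
    tss_margin: int = 3000              # min distance of a TSS from an enhancer
    dhs_rate: float = 0.9               # marker rates on true enhancers
    p300_rate: float = 0.6
    tf_rate: float = 0.5
    marker_length: int = 200
    background_markers_per_chrom: int = 8
    fantom_fraction: float = 0.5
    fantom_length: int = 400
    conserved_rate: float = 0.7
    conserved_length: int = 200
    background_conserved_per_chrom: int = 50
    max_tries: int = 10_000

    def __post_init__(self) -> None:
        for r in (self.gc_background, self.motif_rate,
                  self.lmr_enhancer_fraction, self.vista_fraction,
                  self.dhs_rate, self.p300_rate, self.tf_rate,
                  self.fantom_fraction, self.conserved_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class SimData:
    """In-memory simulation output: the genome plus every companion track."""

    genome: Genome
    truth: list[GenomicInterval]
    lmrs: list[GenomicInterval]
    vista: list[GenomicInterval]
    exons: list[GenomicInterval]
    tss: list[GenomicInterval]
    dhs: list[GenomicInterval]
    p300: list[GenomicInterval]
    tf: list[GenomicInterval]
    fantom: list[GenomicInterval]
    conserved: list[GenomicInterval]
    config: SimConfig


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _place_disjoint(
    rng: np.random.Generator,
    chrom_len: int,
    lengths: list[int],
    margin: int,
    occupied: list[tuple[int, int]],
    max_tries: int,
) -> list[tuple[int, int]]:
    """Uniformly place intervals pairwise >= margin apart from `occupied`."""
    placed: list[tuple[int, int]] = []
    for ln in lengths:
        for _ in range(max_tries):
            start = int(rng.integers(margin, chrom_len - ln - margin))
            end = start + ln
            clash = any(
                start - margin < e and s < end + margin
                for s, e in occupied + placed
            )
            if not clash:
                placed.append((start, end))
                break
        else:
            raise RuntimeError("infeasible placement; relax the configuration")
    return placed


def simulate(cfg: SimConfig) -> SimData:
    """Generate the toy genome and every companion track from one seed."""
    rng = np.random.default_rng(cfg.seed)
    chrom_names = [f"chr{i + 1}" for i in range(len(cfg.chrom_lengths))]

    seqs: dict[str, np.ndarray] = {}
    truth: list[GenomicInterval] = []
    gaps: dict[str, tuple[int, int]] = {}

    for chrom, L in zip(chrom_names, cfg.chrom_lengths):
        codes = _random_sequence(rng, L, cfg.gc_background)
        lengths = [int(rng.integers(*cfg.enhancer_length))
                   for _ in range(cfg.enhancers_per_chrom)]
        occupied: list[tuple[int, int]] = []
        if cfg.n_gap_length > 0:
            gstart = int(rng.integers(cfg.enhancer_margin,
                                      L - cfg.n_gap_length - cfg.enhancer_margin))
            gaps[chrom] = (gstart, gstart + cfg.n_gap_length)
            occupied.append(gaps[chrom])
        spans = _place_disjoint(rng, L, lengths, cfg.enhancer_margin,
                                occupied, cfg.max_tries)
        for ei, (s, e) in enumerate(sorted(spans)):
            truth.append(GenomicInterval(chrom, s, e, name=f"{chrom}_enh{ei}"))
            # plant motif words on a slot grid
            for slot in range(s, e - 6, cfg.motif_spacing):
                if rng.random() < cfg.motif_rate:
                    word = cfg.motifs[int(rng.integers(len(cfg.motifs)))]
                    codes[slot : slot + len(word)] = [
                        "ACGT".index(c) for c in word
                    ]
        seqs[chrom] = codes

    # apply N gaps after planting
    genome_strs = {}
    for chrom in chrom_names:
        arr = _BASES[seqs[chrom]]
        if chrom in gaps:
            g0, g1 = gaps[chrom]
            arr[g0:g1] = "N"
        genome_strs[chrom] = "".join(arr)
    genome = Genome(genome_strs)

    truth_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in truth:
        truth_by_chrom.setdefault(iv.chrom, []).append(iv)

    # --- LMRs: a mix of enhancer-covering and background calls -------------
    n_enh_lmrs = round(cfg.lmr_count * cfg.lmr_enhancer_fraction) if truth else 0
    n_bg_lmrs = cfg.lmr_count - n_enh_lmrs
    lmrs: list[GenomicInterval] = []
    for i in range(n_enh_lmrs):
        enh = truth[int(rng.integers(len(truth)))]
        start = max(0, enh.start + int(rng.integers(-cfg.lmr_jitter,
                                                    cfg.lmr_jitter + 1)))
        end = min(genome.length(enh.chrom),
                  enh.end + int(rng.integers(-cfg.lmr_jitter,
                                             cfg.lmr_jitter + 1)))
        if end - start < 200:
            end = start + 200
        lmrs.append(GenomicInterval(enh.chrom, start, end, name=f"lmr_e{i}"))

    def _away_from_enhancers(chrom: str, start: int, end: int,
                             margin: int) -> bool:
        return all(
            start - margin >= t.end or end + margin <= t.start
            for t in truth_by_chrom.get(chrom, [])
        )

    for i in range(n_bg_lmrs):
        for _ in range(cfg.max_tries):
            ci = int(rng.integers(len(chrom_names)))
            chrom = chrom_names[ci]
            ln = int(rng.integers(*cfg.lmr_background_length))
            start = int(rng.integers(0, genome.length(chrom) - ln))
            end = start + ln
            if _away_from_enhancers(chrom, start, end, 2000) and \
                    "N" not in genome.sequence(chrom)[start:end]:
                lmrs.append(GenomicInterval(chrom, start, end,
                                            name=f"lmr_b{i}"))
                break
        else:
            raise RuntimeError("could not place background LMR")
    lmrs.sort(key=lambda iv: (iv.chrom, iv.start))

    # --- VISTA-like anchors: fragments over a subset of enhancer LMRs ------
    enh_lmrs = [iv for iv in lmrs if iv.name and iv.name.startswith("lmr_e")]
    n_vista = max(5, round(len(enh_lmrs) * cfg.vista_fraction))
    pick = rng.choice(len(enh_lmrs), size=min(n_vista, len(enh_lmrs)),
                      replace=False)
    vista = []
    for j in sorted(pick):
        iv = enh_lmrs[j]
        pad = int(rng.integers(50, 300))
        vista.append(GenomicInterval(
            iv.chrom, max(0, iv.start - pad),
            min(genome.length(iv.chrom), iv.end + pad),
            name=f"vista_{j}",
        ))

    # --- exons (kept away from enhancers so exclusions are meaningful) -----
    exons = []
    for chrom in chrom_names:
        placed = 0
        while placed < cfg.exons_per_chrom:
            ln = int(rng.integers(*cfg.exon_length))
            start = int(rng.integers(0, genome.length(chrom) - ln))
            if _away_from_enhancers(chrom, start, start + ln, 2000):
                exons.append(GenomicInterval(chrom, start, start + ln,
                                             name=f"exon_{chrom}_{placed}"))
                placed += 1
    exons.sort(key=lambda iv: (iv.chrom, iv.start))

    # --- TSS points, at least tss_margin from any enhancer -----------------
    tss = []
    for chrom in chrom_names:
        placed = 0
        while placed < cfg.tss_per_chrom:
            pos = int(rng.integers(0, genome.length(chrom) - 1))
            if _away_from_enhancers(chrom, pos, pos + 1, cfg.tss_margin):
                tss.append(GenomicInterval(chrom, pos, pos + 1,
                                           name=f"tss_{chrom}_{placed}"))
                placed += 1
    tss.sort(key=lambda iv: (iv.chrom, iv.start))

    # --- marker peaks: on-enhancer at the configured rates, plus background
    def _marker_track(rate: float, tag: str) -> list[GenomicInterval]:
        track = []
        for iv in truth:
            if rng.random() < rate:
                center = iv.midpoint + int(rng.integers(-300, 301))
                s = max(0, center - cfg.marker_length // 2)
                track.append(GenomicInterval(
                    iv.chrom, s, s + cfg.marker_length,
                    name=f"{tag}_{iv.name}",
                ))
        for chrom in chrom_names:
            for bi in range(cfg.background_markers_per_chrom):
                start = int(rng.integers(
                    0, genome.length(chrom) - cfg.marker_length))
                track.append(GenomicInterval(
                    chrom, start, start + cfg.marker_length,
                    name=f"{tag}_bg_{chrom}_{bi}",
                ))
        track.sort(key=lambda iv: (iv.chrom, iv.start))
        return track

    dhs = _marker_track(cfg.dhs_rate, "dhs")
    p300 = _marker_track(cfg.p300_rate, "p300")
    tf = _marker_track(cfg.tf_rate, "tf")

    # --- FANTOM-style enhancers: short intervals inside a truth subset -----
    fantom = []
    for iv in truth:
        if rng.random() < cfg.fantom_fraction:
            ln = min(cfg.fantom_length, iv.length)
            s = iv.start + int(rng.integers(0, iv.length - ln + 1))
            fantom.append(GenomicInterval(iv.chrom, s, s + ln,
                                          name=f"fantom_{iv.name}"))

    # --- conserved segments: enhancer midpoints plus dense background ------
    conserved = []
    for iv in truth:
        if rng.random() < cfg.conserved_rate:
            m = iv.midpoint
            s = max(0, m - cfg.conserved_length // 2)
            conserved.append(GenomicInterval(iv.chrom, s,
                                             s + cfg.conserved_length))
    for chrom in chrom_names:
        for _ in range(cfg.background_conserved_per_chrom):
            start = int(rng.integers(
                0, genome.length(chrom) - cfg.conserved_length))
            conserved.append(GenomicInterval(chrom, start,
                                             start + cfg.conserved_length))
    conserved.sort(key=lambda iv: (iv.chrom, iv.start))

    return SimData(genome=genome, truth=truth, lmrs=lmrs, vista=vista,
                   exons=exons, tss=tss, dhs=dhs, p300=p300, tf=tf,
                   fantom=fantom, conserved=conserved, config=cfg)


def write_all(data: SimData, outdir: str | Path) -> dict[str, Path]:
    """Write the genome FASTA and every track as BED into *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"genome": outdir / "genome.fa"}
    write_fasta(data.genome, paths["genome"])
    for key in ("truth", "lmrs", "vista", "exons", "tss", "dhs", "p300",
                "tf", "fantom", "conserved"):
        paths[key] = outdir / f"{key}.bed"
        write_bed(getattr(data, key), paths[key])
    return paths
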