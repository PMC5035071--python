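"""Partition ranked LMRs into RP/LP/LN and build the random negative set.

The unlabeled LMR set is split by density quantile: the top ``delta`` quantiles
are reliable positives (RP), everything below ``ln_quantile`` is likely
negative (LN), the remainder likely positive (LP).  A reliable negative (RN)
set is built by shuffling the LMR locations per chromosome while excluding
exons, the LMRs themselves and any N-containing placement, preserving the
per-chromosome count and length distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from . import kmer
from .genome_io import Genome, GenomicInterval, extract_sequence

__all__ = ["PartitionConfig", "LabeledTraining", "partition",
           "generate_negatives", "assemble_training", "SET_LABELS"]

SET_LABELS = ("RP", "LP", "LN", "RN")


@dataclass(frozen=True)
class PartitionConfig:
    """Quantile cutoffs: RP above ``delta`` (inclusive), LN below ``ln_quantile``."""

    delta: float = 0.95
    ln_quantile: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.delta < 1) or not (0 < self.ln_quantile < 1):
            raise ValueError("cutoffs must lie in (0, 1)")
        if self.ln_quantile >= self.delta:
            raise ValueError("ln_quantile must be < delta")


def partition(ranked, cfg: PartitionConfig) -> list[str]:
    """Set label per ranked LMR: RP iff quantile >= delta, LN iff < ln_quantile."""
    labels = []
    for r in ranked:
        if r.quantile >= cfg.delta:
            labels.append("RP")
        elif r.quantile < cfg.ln_quantile:
            labels.append("LN")
        else:
            labels.append("LP")
    return labels


def generate_negatives(
    template: Sequence[GenomicInterval],
    genome: Genome,
    exclusions: Sequence[GenomicInterval],
    seed: int,
    max_tries: int = 1000,
    allow_self_overlap: bool = False,
) -> list[GenomicInterval]:
    """Shuffle template intervals per chromosome, avoiding exclusions and N.

    One output interval per template interval, on the same chromosome and with
    the same length, uniformly placed by rejection sampling.  Placements must
    not overlap the exclusion set, must contain no N base, and (by default)
    must not overlap previously placed negatives.  An interval that cannot be
    placed within *max_tries* raises, naming the chromosome and length.
    """
    rng = np.random.default_rng(seed)
    trees: dict[str, IntervalTree] = {}
    for iv in exclusions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    placed: dict[str, IntervalTree] = {}

    out: list[GenomicInterval] = []
    for i, tmpl in enumerate(template):
        chrom, length = tmpl.chrom, tmpl.length
        chrom_len = genome.length(chrom)
        if length > chrom_len:
            raise ValueError(
                f"template interval of {length} bp exceeds {chrom} length"
            )
        excl = trees.get(chrom)
        own = placed.setdefault(chrom, IntervalTree())
        for _ in range(max_tries):
            start = int(rng.integers(0, chrom_len - length + 1))
            end = start + length
            if excl is not None and excl.overlap(start, end):
                continue
            if not allow_self_overlap and own.overlap(start, end):
                continue
            seq = genome.sequence(chrom)[start:end]
            if "N" in seq:
                continue
            out.append(GenomicInterval(chrom, start, end, name=f"RN_{i}"))
            own.addi(start, end)
            break
        else:
            raise RuntimeError(
                f"could not place a {length} bp negative on {chrom} "
                f"after {max_tries} tries"
            )
    return out


@dataclass
class LabeledTraining:
    """Encoded training rows with set labels {RP, LP, LN, RN} and y = +/-1."""

    X: np.ndarray                     # (n, 4**k)
    set_labels: np.ndarray            # (n,) of str
    y: np.ndarray                     # (n,) of {+1, -1}
    intervals: list[GenomicInterval]
    k: int

    def __post_init__(self) -> None:
        pos = np.isin(self.set_labels, ("RP", "LP"))
        if not np.array_equal(self.y == 1, pos):
            raise ValueError("class labels inconsistent with set labels")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.set_labels == s)) for s in SET_LABELS}


def assemble_training(
    lmr_labels: Sequence[tuple[GenomicInterval, np.ndarray, str]],
    negatives: Sequence[GenomicInterval],
    genome: Genome,
    k: int = 5,
) -> LabeledTraining:
    """Stack labeled LMR vectors with freshly encoded negative sequences.

    *lmr_labels* carries (interval, k-mer vector, set label in {RP, LP, LN});
    negatives are encoded here and labeled RN.  Invalid encodings (no N-free
    k-mer window) raise, naming the offending interval.
    """
    rows, sets, ivs = [], [], []
    for iv, vec, lab in lmr_labels:
        if lab not in ("RP", "LP", "LN"):
            raise ValueError(f"unexpected LMR set label {lab!r}")
        rows.append(np.asarray(vec, dtype=float))
        sets.append(lab)
        ivs.append(iv)
    for iv in negatives:
        v = kmer.encode(extract_sequence(genome, iv), k)
        if not v.valid:
            raise ValueError(f"negative {iv} has no valid k-mer window")
        rows.append(v.values)
        sets.append("RN")
        ivs.append(iv)
    X = np.vstack(rows)
    set_labels = np.array(sets)
    y = np.where(np.isin(set_labels, ("RP", "LP")), 1, -1)
    return LabeledTraining(X=X, set_labels=set_labels, y=y, intervals=ivs, k=k)
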