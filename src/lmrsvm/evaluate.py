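"""Validation of predicted enhancers against independent marker tracks.

A true-positive marker (TPM) is any DNase-I hypersensitive site, p300 peak or
enhancer-associated TF peak lying more than 1 kb from the nearest TSS.  Each
predicted enhancer (its representative window) is then

* validated     — nearest TPM within 1 kb,
* misclassified — nearest TSS within 2.5 kb but no TPM within 1 kb,
* unknown       — neither.

Validated enhancers fall into six mutually exclusive marker states based on
which of p300 / DHS / TF lies within 1 kb.  Orthogonal checks: overlap with a
CAGE-defined (FANTOM-style) enhancer set by >= 1 bp, and midpoint containment
in conserved segments after excluding exon-overlapping enhancers.  Distances
are edge distances with overlap counting as 0 and thresholds inclusive;
center distance is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportions_ztest

from .genome_io import GenomicInterval, nearest_distance, overlap_select
from .predict import Enhancer, ScoredWindow

__all__ = ["MarkerTracks", "ValidationResult", "build_tpm", "categorize",
           "marker_state", "fantom_overlap_rate", "conserved_midpoint_rate",
           "two_proportion_ztest", "recovery_fscore", "MARKER_STATES"]

MARKER_STATES = ("p300+/-DHS", "DHS only", "TF+DHS", "TF only", "TF+p300",
                 "p300+DHS+TF")


@dataclass
class MarkerTracks:
    """DHS / p300 / TF peak tracks plus TSS points."""

    dhs: list[GenomicInterval]
    p300: list[GenomicInterval]
    tf: list[GenomicInterval]
    tss: list[GenomicInterval]

    @property
    def tpm(self) -> list[GenomicInterval]:
        """The combined marker list (assumes TSS filtering already applied)."""
        return list(self.dhs) + list(self.p300) + list(self.tf)


def collapse_tss(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Model TSSs as 1 bp points: an interval is collapsed to its start base."""
    out = []
    for iv in intervals:
        out.append(GenomicInterval(iv.chrom, iv.start, iv.start + 1, iv.name))
    return out


def build_tpm(
    markers: MarkerTracks, tss_exclusion_bp: int = 1000
) -> tuple[MarkerTracks, dict[str, tuple[int, int]]]:
    """Filter each marker track to sites > *tss_exclusion_bp* from any TSS.

    Distance is the nearest-TSS edge distance; sites on chromosomes with no
    TSS are retained (distance +inf).  Returns the filtered tracks and a
    per-type (kept, total) report.
    """
    if len(markers.tss) == 0:
        raise ValueError("TSS track is empty")

    def keep(track: Sequence[GenomicInterval]) -> list[GenomicInterval]:
        return [
            iv for iv in track
            if nearest_distance(iv, markers.tss, mode="edge") > tss_exclusion_bp
        ]

    dhs, p300, tf = keep(markers.dhs), keep(markers.p300), keep(markers.tf)
    report = {
        "dhs": (len(dhs), len(markers.dhs)),
        "p300": (len(p300), len(markers.p300)),
        "tf": (len(tf), len(markers.tf)),
    }
    return MarkerTracks(dhs=dhs, p300=p300, tf=tf, tss=markers.tss), report


@dataclass
class ValidationResult:
    """Per-enhancer categories and the marker-state breakdown of the validated."""

    categories: list[str]
    states: list[str | None]
    counts: dict[str, int] = field(init=False)
    state_counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.counts = {c: self.categories.count(c)
                       for c in ("validated", "misclassified", "unknown")}
        self.state_counts = {s: self.states.count(s) for s in MARKER_STATES}

    @property
    def n(self) -> int:
        return len(self.categories)

    def percentages(self) -> dict[str, float]:
        if self.n == 0:
            return {c: float("nan") for c in self.counts}
        return {c: 100.0 * v / self.n for c, v in self.counts.items()}


def _within(iv: GenomicInterval, track: Sequence[GenomicInterval],
            bp: int, mode: str) -> bool:
    return nearest_distance(iv, track, mode=mode) <= bp


def marker_state(
    window: ScoredWindow | GenomicInterval,
    dhs: Sequence[GenomicInterval],
    p300: Sequence[GenomicInterval],
    tf: Sequence[GenomicInterval],
    tpm_bp: int = 1000,
    mode: str = "edge",
) -> str:
    """The six-state marker label of a validated enhancer.

    p300 presence without TF collapses 'p300+DHS' and 'p300' into 'p300+/-DHS'.
    """
    iv = window.interval if isinstance(window, ScoredWindow) else window
    has_p300 = _within(iv, p300, tpm_bp, mode)
    has_dhs = _within(iv, dhs, tpm_bp, mode)
    has_tf = _within(iv, tf, tpm_bp, mode)
    triple = (has_p300, has_dhs, has_tf)
    if triple == (False, False, False):
        raise ValueError("validated enhancer with no marker within range")
    if has_p300 and not has_tf:
        return "p300+/-DHS"
    if triple == (False, True, False):
        return "DHS only"
    if triple == (False, True, True):
        return "TF+DHS"
    if triple == (False, False, True):
        return "TF only"
    if triple == (True, False, True):
        return "TF+p300"
    return "p300+DHS+TF"


def categorize(
    windows: Sequence[ScoredWindow],
    tpm: MarkerTracks,
    tpm_bp: int = 1000,
    tss_bp: int = 2500,
    mode: str = "edge",
) -> ValidationResult:
    """Label each representative window validated / misclassified / unknown.

    *tpm* must already be TSS-filtered (see :func:`build_tpm`).  Rules are
    applied in order: a TPM within *tpm_bp* validates; otherwise a TSS within
    *tss_bp* marks misclassification; otherwise unknown.  Thresholds are
    inclusive.
    """
    tpm_track = tpm.tpm
    categories: list[str] = []
    states: list[str | None] = []
    for w in windows:
        iv = w.interval
        if _within(iv, tpm_track, tpm_bp, mode):
            categories.append("validated")
            states.append(
                marker_state(iv, tpm.dhs, tpm.p300, tpm.tf, tpm_bp, mode)
            )
        elif _within(iv, tpm.tss, tss_bp, mode):
            categories.append("misclassified")
            states.append(None)
        else:
            categories.append("unknown")
            states.append(None)
    return ValidationResult(categories=categories, states=states)


def fantom_overlap_rate(
    windows: Sequence[ScoredWindow | GenomicInterval],
    fantom: Sequence[GenomicInterval],
) -> float:
    """Fraction of windows overlapping a FANTOM-style enhancer by >= 1 bp."""
    if len(windows) == 0:
        return 0.0
    ivs = [w.interval if isinstance(w, ScoredWindow) else w for w in windows]
    hits = overlap_select(ivs, list(fantom), min_bp=1)
    return len(hits) / len(ivs)


def conserved_midpoint_rate(
    enhancers: Sequence[Enhancer | GenomicInterval],
    conserved: Sequence[GenomicInterval],
    exons: Sequence[GenomicInterval],
) -> float:
    """Fraction of exon-free enhancers whose 1 bp midpoint lies in a
    conserved segment.

    Enhancers overlapping any exon are removed first (a 2 kb window easily
    hits a conserved segment by chance; the midpoint rule avoids that
    inflation).  NaN when every enhancer is exon-overlapping.
    """
    ivs = [e.interval if isinstance(e, Enhancer) else e for e in enhancers]
    exonic = set(
        id(iv) for iv in overlap_select(ivs, list(exons), min_bp=1)
    )
    retained = [iv for iv in ivs if id(iv) not in exonic]
    if not retained:
        return float("nan")
    midpoints = [
        GenomicInterval(iv.chrom, iv.midpoint, iv.midpoint + 1)
        for iv in retained
    ]
    hits = overlap_select(midpoints, list(conserved), min_bp=1)
    return len(hits) / len(retained)


def two_proportion_ztest(
    x1: int, n1: int, x2: int, n2: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Pooled-variance two-proportion z-test; returns (z, p).

    NaN for both when the pooled variance is zero (all successes or all
    failures).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not (0 <= x <= n):
            raise ValueError("need 0 <= x <= n and n > 0")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return float("nan"), float("nan")
    alt = {"two-sided": "two-sided", "larger": "larger",
           "smaller": "smaller"}[alternative]
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative=alt)
    return float(z), float(p)


def recovery_fscore(
    windows: Sequence[ScoredWindow | GenomicInterval],
    truth: Sequence[GenomicInterval],
) -> "CvMetricsLike":
    """Precision/recall/F of representative windows against a truth track.

    A window is a true positive when it overlaps a truth interval by >= 1 bp;
    a truth interval is recovered when some window overlaps it.  Used for
    benchmarking on simulated genomes where the planted enhancers are known.
    """
    ivs = [w.interval if isinstance(w, ScoredWindow) else w for w in windows]
    tp_windows = len(overlap_select(ivs, list(truth), min_bp=1))
    recovered = len(overlap_select(list(truth), ivs, min_bp=1))
    precision = tp_windows / len(ivs) if ivs else 0.0
    recall = recovered / len(truth) if truth else 0.0
    f = (2 * precision * recall / (precision + recall)
         if precision + recall > 0 else 0.0)
    return CvMetricsLike(precision=precision, recall=recall, f=f,
                         n_windows=len(ivs), n_truth=len(truth))


@dataclass
class CvMetricsLike:
    precision: float
    recall: float
    f: float
    n_windows: int
    n_truth: int
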