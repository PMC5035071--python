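"""Sliding-window genome scanning and merging of positive windows.

The trained linear model scores fixed-size windows (default 2 kb, tiled every
500 bp from position 0 of each chromosome).  Windows with positive decision
values are enhancer windows; overlapping or adjacent positive windows are
joined into one reported enhancer, optionally split where a fully negative
window lies between two positive ones.  Each enhancer's highest-scoring member
window is its representative for downstream per-enhancer evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import kmer
from .genome_io import Genome, GenomicInterval
from .wsvm import WsvmModel

__all__ = ["ScoredWindow", "Enhancer", "scan", "merge", "representatives"]


@dataclass(frozen=True)
class ScoredWindow:
    """One scan window with its decision value.

    ``callable_window`` is False when the window had no N-free k-mer (an
    assembly-gap desert); such windows carry score -inf and are never treated
    as confident negatives when splitting merged enhancers.
    """

    interval: GenomicInterval
    score: float
    callable_window: bool = True

    @property
    def positive(self) -> bool:
        return self.score > 0


@dataclass
class Enhancer:
    """A merged run of positive windows; the union span is the reported locus."""

    interval: GenomicInterval
    members: list[ScoredWindow]

    @property
    def representative(self) -> ScoredWindow:
        """Highest-scoring member; leftmost on ties."""
        return max(self.members, key=lambda w: (w.score, -w.interval.start))


def scan(
    model: WsvmModel,
    genome: Genome,
    window: int = 2000,
    step: int = 500,
    chroms: Sequence[str] | None = None,
) -> list[ScoredWindow]:
    """Score every window tiled at starts 0, step, 2*step, ... per chromosome.

    A trailing partial window is not emitted; chromosomes shorter than the
    window produce zero windows with a warning.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if window < model.k:
        raise ValueError("window must be at least k")
    out: list[ScoredWindow] = []
    for chrom in (chroms if chroms is not None else genome.chroms):
        L = genome.length(chrom)
        if L < window:
            warnings.warn(
                f"{chrom} ({L} bp) shorter than window {window}; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        seq = genome.sequence(chrom)
        for start in range(0, L - window + 1, step):
            v = kmer.encode(seq[start : start + window], model.k)
            iv = GenomicInterval(chrom, start, start + window)
            if v.valid:
                score = float(v.values @ model.w + model.b)
                out.append(ScoredWindow(iv, score, True))
            else:
                out.append(ScoredWindow(iv, float("-inf"), False))
    return out


def _split_points(
    positives: list[ScoredWindow], negatives: list[ScoredWindow]
) -> list[int]:
    """Cut positions inside one connected component of positive windows.

    A cut is placed at the midpoint of a negative (callable) window lying
    within the component span, unless some positive member spans that
    midpoint.
    """
    cuts = []
    span_start = min(w.interval.start for w in positives)
    span_end = max(w.interval.end for w in positives)
    for neg in negatives:
        m = neg.interval.midpoint
        if not (span_start < m < span_end):
            continue
        if any(w.interval.start < m < w.interval.end for w in positives):
            continue
        cuts.append(m)
    return sorted(set(cuts))


def merge(
    windows: Sequence[ScoredWindow], split_at_negative: bool = True
) -> list[Enhancer]:
    """Join positive windows into enhancers.

    Positive windows are grouped into connected components under
    overlap-or-adjacency (a shared base or touching ends chains two windows).
    With *split_at_negative*, a component is additionally split at the
    midpoint of an intervening fully negative window that no positive member
    spans.  Non-callable (all-N) windows never cause splits.
    """
    by_chrom: dict[str, list[ScoredWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.interval.chrom, []).append(w)

    out: list[Enhancer] = []
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: (w.interval.start,
                                                    w.interval.end))
        positives = [w for w in ws if w.positive]
        negatives = [w for w in ws if (not w.positive) and w.callable_window]
        # connected components under overlap-or-adjacency
        comp: list[ScoredWindow] = []
        comp_end = None
        comps: list[list[ScoredWindow]] = []
        for w in positives:
            if comp_end is None or w.interval.start <= comp_end:
                comp.append(w)
                comp_end = max(comp_end or 0, w.interval.end)
            else:
                comps.append(comp)
                comp = [w]
                comp_end = w.interval.end
        if comp:
            comps.append(comp)

        for members in comps:
            pieces = [members]
            if split_at_negative:
                cuts = _split_points(members, negatives)
                for cut in cuts:
                    last = pieces.pop()
                    left = [w for w in last if w.interval.end <= cut]
                    right = [w for w in last if w.interval.start >= cut]
                    if left and right:
                        pieces.extend([left, right])
                    else:
                        pieces.append(last)
            for piece in pieces:
                iv = GenomicInterval(
                    chrom,
                    min(w.interval.start for w in piece),
                    max(w.interval.end for w in piece),
                )
                out.append(Enhancer(interval=iv, members=piece))
    return out


def representatives(enhancers: Iterable[Enhancer]) -> list[ScoredWindow]:
    """One representative window per enhancer (max score, leftmost tie)."""
    return [e.representative for e in enhancers]
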