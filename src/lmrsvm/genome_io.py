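"""FASTA/BED input-output and interval arithmetic.

Every genomic location in the package is a :class:`GenomicInterval` using the
BED convention: 0-based, half-open ``[start, end)``.  Touching intervals never
overlap.  Sequences are handled on the plus strand and uppercased on read, so
soft-masking is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree
from pyfaidx import Fasta

__all__ = [
    "GenomicInterval",
    "Genome",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "extract_sequence",
    "filter_by_length",
    "overlap_select",
    "overlap_length",
    "nearest_distance",
]


class BedParseError(ValueError):
    """Raised on malformed BED records; carries the 1-based line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """The 1 bp midpoint position (floor of the center)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and overlap_length(self, other) > 0

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the intersection of two intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class Genome:
    """An in-memory genome: ordered map of chromosome name to sequence.

    Sequences are uppercase over the alphabet {A, C, G, T, N}.  All interval
    operations validate the chromosome name and bounds.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        self._check_chrom(chrom)
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        self._check_chrom(chrom)
        return self._seqs[chrom]

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())


def read_fasta(path: str | Path) -> Genome:
    """Load a (multi-record, wrapped or unwrapped) FASTA into memory."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    genome = Genome({name: str(fa[name][:]) for name in fa.keys()})
    fa.close()
    return genome


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_sequence(genome: Genome, iv: GenomicInterval) -> str:
    """Plus-strand subsequence for *iv*, uppercased; errors when out of bounds."""
    n = genome.length(iv.chrom)
    if iv.end > n:
        raise ValueError(
            f"interval {iv} out of bounds for {iv.chrom} (length {n})"
        )
    return genome.sequence(iv.chrom)[iv.start : iv.end]


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse a BED3/BED5/BED6 file into intervals, in file order.

    Columns 4 and 5 are mapped to ``name`` and ``score`` when present.
    Malformed lines raise :class:`BedParseError` naming the 1-based line.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates: {exc}"
                ) from None
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score = None
            if len(cols) > 4 and cols[4] != ".":
                try:
                    score = float(cols[4])
                except ValueError:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score {cols[4]!r}"
                    ) from None
            try:
                out.append(GenomicInterval(cols[0], start, end, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(
    ivs: Iterable[GenomicInterval], path: str | Path, score_fmt: str = "%.6f"
) -> None:
    """Write BED3/BED5 records; name/score columns emitted when present."""
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(score_fmt % iv.score)
            fh.write("\t".join(cols) + "\n")


def filter_by_length(
    ivs: Sequence[GenomicInterval], min_bp: int = 200, max_bp: int = 3000
) -> list[GenomicInterval]:
    """Keep intervals with ``min_bp <= length <= max_bp`` (inclusive bounds).

    Defaults drop candidate regions shorter than 200 bp or longer than 3 kb
    before model training.
    """
    if min_bp > max_bp:
        raise ValueError("min_bp must be <= max_bp")
    return [iv for iv in ivs if min_bp <= iv.length <= max_bp]


def _build_trees(ivs: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in ivs:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def overlap_select(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> list[GenomicInterval]:
    """Subset of *a* overlapping some interval of *b* by at least *min_bp*.

    One-way overlap on the *a* side; same-chromosome only; order preserved.
    """
    trees = _build_trees(b)
    out = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = tree.overlap(iv.start, iv.end)
        if any(min(iv.end, h.end) - max(iv.start, h.begin) >= min_bp for h in hits):
            out.append(iv)
    return out


def nearest_distance(
    iv: GenomicInterval,
    anchors: Sequence[GenomicInterval],
    mode: str = "edge",
) -> float:
    """Distance in bp from *iv* to its nearest same-chromosome anchor.

    ``mode="center"`` measures |midpoint - midpoint|; ``mode="edge"`` measures
    the gap between closest edges (0 when the intervals overlap or touch).
    Returns ``inf`` when no anchor shares the chromosome.
    """
    if mode not in ("center", "edge"):
        raise ValueError(f"unknown mode {mode!r}")
    best = math.inf
    for a in anchors:
        if a.chrom != iv.chrom:
            continue
        if mode == "center":
            d = abs(iv.midpoint - a.midpoint)
        else:
            d = max(iv.start - a.end, a.start - iv.end, 0)
        best = min(best, d)
        if best == 0:
            return 0.0
    return best
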