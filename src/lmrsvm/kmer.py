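"""k-mer sequence encoding.

Each DNA sequence is represented by the vector of counts of all overlapping
length-k words over {A, C, G, T}, indexed lexicographically (A=0, C=1, G=2,
T=3, most-significant first) and normalized to sum to one.  Windows containing
an ambiguous base (N) are skipped; a sequence with no valid window yields an
all-zero vector flagged invalid rather than an exception, so observed regions
that happen to straddle assembly gaps degrade gracefully.

The default word length is k = 5 (1,024 dimensions).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["KmerVector", "kmer_index", "kmer_word", "encode", "encode_batch",
           "gc_content", "write_matrix_tsv"]

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int64)  # A<->T, C<->G


@dataclass
class KmerVector:
    """Normalized k-mer composition of one sequence."""

    k: int
    values: np.ndarray
    source_length: int

    @property
    def valid(self) -> bool:
        """True when the source had at least one N-free k-mer window."""
        return bool(self.values.sum() > 0)


def kmer_index(word: str) -> int:
    """Lexicographic index of a k-mer (bijective on {A,C,G,T}^k)."""
    codes = _CODE[np.frombuffer(word.encode("ascii"), dtype=np.uint8)]
    if (codes >= 4).any():
        raise ValueError(f"word {word!r} contains non-ACGT characters")
    idx = 0
    for c in codes:
        idx = idx * 4 + int(c)
    return idx


def kmer_word(index: int, k: int) -> str:
    """Inverse of :func:`kmer_index`."""
    if not 0 <= index < 4**k:
        raise ValueError("index out of range")
    letters = []
    for _ in range(k):
        letters.append("ACGT"[index % 4])
        index //= 4
    return "".join(reversed(letters))


def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_indices(codes: np.ndarray, k: int) -> np.ndarray:
    """Indices of all N-free k-mer windows of a coded sequence."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    idx = np.zeros(m, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + codes[j : j + m]
    bad = codes >= 4
    if bad.any():
        # a window is invalid iff it contains any N position
        cs = np.concatenate(([0], np.cumsum(bad)))
        invalid = (cs[k:] - cs[:-k]) > 0
        return idx[~invalid]
    return idx


def raw_counts(seq: str, k: int = 5, canonical: bool = False) -> np.ndarray:
    """Unnormalized k-mer counts (integer vector of length 4**k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = _codes(seq)
    idx = _window_indices(codes, k)
    counts = np.bincount(idx, minlength=4**k).astype(np.int64)
    if canonical:
        # collapse each word with its reverse complement onto the smaller index
        rc = _revcomp_index_table(k)
        collapsed = np.zeros_like(counts)
        lo = np.minimum(np.arange(4**k), rc)
        np.add.at(collapsed, lo, counts)
        counts = collapsed
    return counts


_RC_CACHE: dict[int, np.ndarray] = {}


def _revcomp_index_table(k: int) -> np.ndarray:
    if k not in _RC_CACHE:
        idx = np.arange(4**k)
        rc = np.zeros_like(idx)
        rem = idx.copy()
        for _ in range(k):
            rc = rc * 4 + (3 - rem % 4)
            rem //= 4
        _RC_CACHE[k] = rc
    return _RC_CACHE[k]


def encode(seq: str, k: int = 5, canonical: bool = False) -> KmerVector:
    """Encode one sequence as a normalized k-mer vector.

    Windows containing N are skipped; with zero valid windows the vector is
    all-zero and ``.valid`` is False.
    """
    counts = raw_counts(seq, k, canonical=canonical)
    total = counts.sum()
    values = counts / total if total > 0 else counts.astype(float)
    return KmerVector(k=k, values=values, source_length=len(seq))


def encode_batch(
    seqs: Sequence[str], k: int = 5, canonical: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences row-wise: (n x 4**k) matrix plus validity mask."""
    if len(seqs) == 0:
        raise ValueError("empty batch")
    mat = np.zeros((len(seqs), 4**k))
    mask = np.zeros(len(seqs), dtype=bool)
    for i, s in enumerate(seqs):
        v = encode(s, k, canonical=canonical)
        mat[i] = v.values
        mask[i] = v.valid
    return mat, mask


def gc_content(seq: str) -> float:
    """(G + C) / non-N bases; NaN for an all-N sequence; error when empty."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    codes = _codes(seq)
    denom = int((codes < 4).sum())
    if denom == 0:
        return float("nan")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / denom


def write_matrix_tsv(
    ids: Sequence[str], matrix: np.ndarray, k: int, path: str | Path
) -> None:
    """Export an encoded matrix (row = sequence id, 4**k columns) as TSV."""
    header = "id\t" + "\t".join(kmer_word(i, k) for i in range(4**k))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for rid, row in zip(ids, matrix):
            fh.write(rid + "\t" + "\t".join("%.10g" % v for v in row) + "\n")
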