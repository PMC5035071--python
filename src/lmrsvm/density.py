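"""Nonparametric density ranking of candidate regions in k-mer space.

A kernel density estimate is fitted on the anchor set (the LMRs that overlap
validated enhancers) and every LMR is ranked by its estimated density: the
higher the density, the more the sequence resembles the anchors.  Normalized
ranks (quantiles) drive the RP / LP / LN partition downstream.

Raw 4**k-dimensional k-mer space is far too wide for a KDE on ~100 anchors,
so anchors are first projected with PCA onto the leading components explaining
a configurable fraction of variance (default 95%); queries are mapped through
the same projection.  The kernel is a product Gaussian with a per-dimension
Silverman bandwidth.  Both choices are recorded on the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.decomposition import PCA

from .genome_io import GenomicInterval

__all__ = ["DensityModel", "RankedLmr", "fit_density", "rank_by_density",
           "rank_order"]

MIN_ANCHORS = 5


@dataclass
class RankedLmr:
    """An LMR with its density under the anchor KDE, rank and quantile.

    Rank 1 is the *lowest* density; quantile = rank / n, so the most
    anchor-like regions sit at quantile 1.
    """

    interval: GenomicInterval
    vector: np.ndarray
    density: float
    log_density: float
    rank: int
    quantile: float


@dataclass
class DensityModel:
    """Product-Gaussian KDE over PCA-projected anchor k-mer vectors."""

    anchors_projected: np.ndarray          # (m, q)
    bandwidths: np.ndarray                 # (q,)
    pca: PCA | None                        # None when no projection was used
    n_components: int
    explained_variance: float

    @property
    def n_anchors(self) -> int:
        return self.anchors_projected.shape[0]

    def project(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.pca is not None:
            return self.pca.transform(X)
        return X

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """Log KDE density for each row of X (in the original feature space)."""
        Z = self.project(X)
        if Z.shape[1] != self.anchors_projected.shape[1]:
            raise ValueError(
                f"dimension mismatch: query {Z.shape[1]} vs model "
                f"{self.anchors_projected.shape[1]}"
            )
        h = self.bandwidths
        m = self.n_anchors
        # log of (1/m) sum_a prod_j N(z_j - a_j; h_j)
        const = -0.5 * np.sum(np.log(2 * np.pi * h**2)) - np.log(m)
        diff = (Z[:, None, :] - self.anchors_projected[None, :, :]) / h
        sq = -0.5 * np.sum(diff**2, axis=2)          # (n, m)
        return logsumexp(sq, axis=1) + const

    def density(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(X))


def fit_density(
    anchors: np.ndarray,
    variance_retained: float = 0.95,
    reduce_dim: int | None = None,
    min_bandwidth: float = 1e-8,
) -> DensityModel:
    """Fit the anchor KDE.

    Parameters
    ----------
    anchors : (m, d) matrix of anchor k-mer vectors, m >= 5.
    variance_retained : choose the smallest PCA dimension whose cumulative
        explained variance reaches this fraction (ignored when *reduce_dim*
        is given).
    reduce_dim : explicit number of retained components; ``0`` disables the
        projection entirely.
    min_bandwidth : floor applied per dimension so duplicate or constant
        anchors still give a finite, positive density (with a warning).
    """
    A = np.asarray(anchors, dtype=float)
    if A.ndim != 2 or A.shape[0] < MIN_ANCHORS:
        raise ValueError(f"need at least {MIN_ANCHORS} anchor vectors")
    m, d = A.shape

    pca: PCA | None = None
    if reduce_dim == 0:
        Z = A
        explained = 1.0
    else:
        max_q = min(m - 1, d)
        if reduce_dim is not None:
            q = min(reduce_dim, max_q)
        else:
            q = max_q
        full = PCA(n_components=min(max_q, m - 1), svd_solver="full")
        full.fit(A)
        if reduce_dim is None:
            ratios = np.cumsum(full.explained_variance_ratio_)
            if np.all(~np.isfinite(ratios)) or ratios[-1] <= 0:
                q = 1
            else:
                q = int(np.searchsorted(ratios, variance_retained) + 1)
                q = min(q, len(ratios))
        pca = PCA(n_components=q, svd_solver="full")
        Z = pca.fit_transform(A)
        explained = float(np.sum(pca.explained_variance_ratio_))

    q = Z.shape[1]
    sigma = Z.std(axis=0, ddof=1) if m > 1 else np.zeros(q)
    # Silverman's rule per retained dimension
    factor = (4.0 / ((q + 2) * m)) ** (1.0 / (q + 4))
    h = sigma * factor
    if np.any(h < min_bandwidth):
        warnings.warn(
            "near-zero anchor variance in some dimensions; bandwidth floored",
            RuntimeWarning,
            stacklevel=2,
        )
        h = np.maximum(h, min_bandwidth)
    return DensityModel(
        anchors_projected=Z,
        bandwidths=h,
        pca=pca,
        n_components=q,
        explained_variance=explained,
    )


def rank_order(
    densities: Sequence[float], intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Deterministic ascending rank order: ties broken by (chrom, start, end).

    Returns the permutation ``order`` such that ``order[0]`` is the index of
    the lowest-density item.  Any strictly increasing transform of the
    densities yields the same order.
    """
    keys = [
        (float(densities[i]), intervals[i].chrom, intervals[i].start,
         intervals[i].end)
        for i in range(len(densities))
    ]
    return np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=int)


def rank_by_density(
    model: DensityModel,
    lmrs: Sequence[tuple[GenomicInterval, np.ndarray]],
) -> list[RankedLmr]:
    """Evaluate each LMR's density under the model and assign rank/quantile."""
    if len(lmrs) == 0:
        return []
    intervals = [iv for iv, _ in lmrs]
    X = np.vstack([np.asarray(v, dtype=float) for _, v in lmrs])
    logd = model.log_density(X)
    if not np.all(np.isfinite(logd)):
        raise ValueError("non-finite density encountered")
    order = rank_order(logd, intervals)
    n = len(lmrs)
    out: list[RankedLmr] = [None] * n  # type: ignore[list-item]
    for rank_minus_1, idx in enumerate(order):
        rank = rank_minus_1 + 1
        out[idx] = RankedLmr(
            interval=intervals[idx],
            vector=X[idx],
            density=float(np.exp(logd[idx])),
            log_density=float(logd[idx]),
            rank=rank,
            quantile=rank / n,
        )
    return out
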