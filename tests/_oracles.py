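"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
package's own: dictionary loops instead of vectorized counting, quadratic
scans instead of interval trees, a generic QP solve instead of SMO.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def dict_kmer_counts(seq: str, k: int) -> dict[str, int]:
    """Count N-free k-mers with a plain dictionary loop."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if set(word) <= set("ACGT"):
            counts[word] = counts.get(word, 0) + 1
    return counts


def brute_overlap_len(a, b) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def brute_overlap_select(a_list, b_list, min_bp=1):
    return [
        a for a in a_list
        if any(brute_overlap_len(a, b) >= min_bp for b in b_list)
    ]


def brute_nearest_edge(iv, anchors) -> float:
    best = float("inf")
    for a in anchors:
        if a.chrom != iv.chrom:
            continue
        if brute_overlap_len(iv, a) > 0:
            return 0.0
        best = min(best, max(iv.start - a.end, a.start - iv.end))
    return best


def union_find_components(windows):
    """Connected components of positive windows under overlap-or-adjacency,
    via quadratic union-find."""
    pos = [w for w in windows if w.score > 0]
    parent = list(range(len(pos)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            a, b = pos[i].interval, pos[j].interval
            if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                parent[find(i)] = find(j)
    comps: dict[int, list] = {}
    for i, w in enumerate(pos):
        comps.setdefault(find(i), []).append(w)
    spans = sorted(
        (ws[0].interval.chrom,
         min(w.interval.start for w in ws),
         max(w.interval.end for w in ws))
        for ws in comps.values()
    )
    return spans


def qp_svm_reference(X: np.ndarray, y: np.ndarray, C: np.ndarray):
    """C-SVM with per-sample costs, solved by a generic dual QP (SLSQP)
    followed by an exact KKT polish on the identified active set.

    Returns (w, b, primal objective).
    """
    n = len(y)
    yf = y.astype(float)
    K = X @ X.T
    Q = K * np.outer(yf, yf)
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.zeros(n),
        jac=lambda a: Q @ a - 1,
        method="SLSQP",
        bounds=[(0, c) for c in C],
        constraints=[{"type": "eq", "fun": lambda a: a @ yf,
                      "jac": lambda a: yf}],
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    a = res.x
    tol_a = 1e-6 * C
    free = (a > tol_a) & (a < C - tol_a)
    at_c = a >= C - tol_a
    F = np.flatnonzero(free)
    B = np.flatnonzero(at_c)
    if len(F) == 0:
        w = X.T @ (a * yf)
        b = 0.0
    else:
        A = np.zeros((len(F) + 1, len(F) + 1))
        A[: len(F), : len(F)] = K[np.ix_(F, F)] * yf[F][None, :]
        A[: len(F), -1] = 1.0
        A[-1, : len(F)] = yf[F]
        rhs_top = yf[F] - (K[np.ix_(F, B)] @ (yf[B] * C[B]) if len(B) else 0.0)
        rhs = np.concatenate([np.atleast_1d(rhs_top),
                              [-(yf[B] @ C[B]) if len(B) else 0.0]])
        sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
        a2 = np.zeros(n)
        a2[F] = sol[: len(F)]
        a2[B] = C[B]
        w = X.T @ (a2 * yf)
        b = float(sol[-1])
    obj = float(0.5 * w @ w + C @ np.maximum(0.0, 1.0 - yf * (X @ w + b)))
    return w, b, obj


def gaussian_mixture_density(X, means, covs, weights):
    """Closed-form density of a Gaussian mixture at each row of X."""
    from scipy.stats import multivariate_normal

    X = np.atleast_2d(X)
    dens = np.zeros(X.shape[0])
    for mu, cov, wt in zip(means, covs, weights):
        dens += wt * multivariate_normal.pdf(X, mean=mu, cov=cov)
    return dens
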