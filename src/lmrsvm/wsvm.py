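"""Four-weight soft-margin linear SVM and the CV model-selection protocol.

The classifier solves

    min_{w,b,xi}  1/2 ||w||^2 + sum_i C_i xi_i
    s.t.          y_i (w.x_i + b) >= 1 - xi_i,   xi_i >= 0

where each sample's misclassification cost C_i is one of four penalties
determined by its training-set membership: C_RP, C_LP (positives) and C_LN,
C_RN (negatives), with C_RP >= C_LP and C_RN >= C_LN reflecting higher
confidence in the reliable sets.  The dual is solved by SMO with
maximal-violating-pair working-set selection and a per-sample box, which
reduces to the standard C-SVM when all four penalties coincide.

Model selection runs stratified 5-fold cross-validation over a grid of
(delta, weights): candidates are scored by fold-pooled F over the RP/LP
positives, candidates whose retrained model covers more than a capped
fraction of a proxy chromosome are discarded, and among the top-F tie group
the highest-precision candidate wins.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .genome_io import Genome
from .labeling import LabeledTraining, PartitionConfig, partition

__all__ = ["WsvmWeights", "WsvmModel", "CvMetrics", "train", "fscore",
           "genomic_coverage", "choose_best", "select_model",
           "SelectionReportRow", "SelectionResult", "save_model", "load_model"]


@dataclass(frozen=True)
class WsvmWeights:
    """The four set penalties; reliable sets must outweigh likely sets."""

    c_rp: float
    c_lp: float
    c_ln: float
    c_rn: float

    def __post_init__(self) -> None:
        for v in (self.c_rp, self.c_lp, self.c_ln, self.c_rn):
            if not v > 0:
                raise ValueError("all penalties must be positive")
        if self.c_rp < self.c_lp:
            raise ValueError("need C_RP >= C_LP")
        if self.c_rn < self.c_ln:
            raise ValueError("need C_RN >= C_LN")

    def per_sample(self, set_labels: np.ndarray) -> np.ndarray:
        lut = {"RP": self.c_rp, "LP": self.c_lp, "LN": self.c_ln,
               "RN": self.c_rn}
        return np.array([lut[s] for s in set_labels])

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.c_rp, self.c_lp, self.c_ln, self.c_rn)


@dataclass
class WsvmModel:
    """A trained linear model: decision score(x) = w.x + b."""

    w: np.ndarray
    b: float
    weights: WsvmWeights
    k: int
    alpha: np.ndarray | None = None
    kkt_gap: float = float("nan")
    delta: float | None = None

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.w + self.b

    def slacks(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, 1.0 - y * self.decision(X))

    def primal_objective(self, X: np.ndarray, y: np.ndarray,
                         C: np.ndarray) -> float:
        return float(0.5 * self.w @ self.w + C @ self.slacks(X, y))


def _smo(
    K: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, float, int]:
    """SMO on the dual with per-sample box [0, C_i].

    Working-set selection is the maximal violating pair.  Returns
    (alpha, b, final KKT violation m - M, iterations).
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    F = np.zeros(n)                      # F_i = sum_l y_l alpha_l K_il
    yF = y - F                           # selection scores
    it = 0
    while it < max_iter:
        up = ((y == 1) & (alpha < C)) | ((y == -1) & (alpha > 0))
        lo = ((y == 1) & (alpha > 0)) | ((y == -1) & (alpha < C))
        if not up.any() or not lo.any():
            break
        yF = y - F
        i = int(np.flatnonzero(up)[np.argmax(yF[up])])
        j = int(np.flatnonzero(lo)[np.argmin(yF[lo])])
        viol = yF[i] - yF[j]
        if viol <= tol:
            break
        yi, yj = y[i], y[j]
        ai_old, aj_old = alpha[i], alpha[j]
        if yi != yj:
            L = max(0.0, aj_old - ai_old)
            H = min(C[j], C[i] + aj_old - ai_old)
        else:
            L = max(0.0, ai_old + aj_old - C[i])
            H = min(C[j], ai_old + aj_old)
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        Ei = F[i] - yi
        Ej = F[j] - yj
        if eta > 1e-15:
            aj = aj_old + yj * (Ei - Ej) / eta
            aj = min(max(aj, L), H)
        else:
            # flat direction: move to whichever bound improves the objective
            aj = L if yj * (Ei - Ej) > 0 else H
        if abs(aj - aj_old) < 1e-14:
            # degenerate box for the maximal violating pair; no progress possible
            break
        ai = ai_old + yi * yj * (aj_old - aj)
        # snap to the box so bound-riding values do not masquerade as free
        if ai < 1e-12:
            ai = 0.0
        elif ai > C[i] - 1e-12:
            ai = C[i]
        if aj < 1e-12:
            aj = 0.0
        elif aj > C[j] - 1e-12:
            aj = C[j]
        alpha[i], alpha[j] = ai, aj
        F += yi * (ai - ai_old) * K[:, i] + yj * (aj - aj_old) * K[:, j]
        it += 1

    yF = y - F
    up = ((y == 1) & (alpha < C)) | ((y == -1) & (alpha > 0))
    lo = ((y == 1) & (alpha > 0)) | ((y == -1) & (alpha < C))
    m = float(np.max(yF[up])) if up.any() else -np.inf
    M = float(np.min(yF[lo])) if lo.any() else np.inf
    free = (alpha > 1e-12) & (alpha < C - 1e-12)
    if free.any():
        b = float(np.mean(yF[free]))
    else:
        b = (m + M) / 2.0
        if not np.isfinite(b):
            b = 0.0
    return alpha, b, m - M, it


def train(
    data: LabeledTraining,
    weights: WsvmWeights,
    tol: float = 1e-6,
    max_iter: int = 2_000_000,
) -> WsvmModel:
    """Solve the four-weight SVM on *data*; optimum certified by KKT gap <= tol."""
    y = data.y.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    C = weights.per_sample(data.set_labels)
    X = data.X
    K = X @ X.T
    alpha, b, gap, it = _smo(K, y, C, tol, max_iter)
    if gap > tol:
        raise RuntimeError(
            f"SMO did not converge: KKT violation {gap:.3g} after {it} iterations"
        )
    w = X.T @ (alpha * y)
    return WsvmModel(w=w, b=b, weights=weights, k=data.k, alpha=alpha,
                     kkt_gap=float(max(gap, 0.0)))


@dataclass
class CvMetrics:
    """Pooled confusion counts over RP/LP positives and derived scores."""

    tp: int
    fn: int
    pp: int
    coverage: float = float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else 0.0

    @property
    def precision(self) -> float:
        return self.tp / self.pp if self.pp > 0 else 0.0

    @property
    def f(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


def fscore(tp: int, fn: int, pp: int) -> CvMetrics:
    """F-score over the unlabeled-positive protocol.

    TP and FN count RP/LP sequences predicted positive and negative; PP counts
    all sequences predicted positive (including LN/RN false positives).
    Degenerate denominators yield 0.
    """
    if min(tp, fn, pp) < 0:
        raise ValueError("counts must be non-negative")
    return CvMetrics(tp=tp, fn=fn, pp=pp)


def genomic_coverage(
    model: WsvmModel,
    genome: Genome,
    proxy_chrom: str,
    window: int = 2000,
    step: int = 500,
) -> float:
    """Fraction of the proxy chromosome covered by predicted enhancers.

    Scans the proxy chromosome, merges positive windows and divides covered bp
    by chromosome length — the single-chromosome proxy for genome-wide
    coverage used during model selection.
    """
    from . import predict  # local import to avoid a module cycle

    if proxy_chrom not in genome:
        raise KeyError(f"proxy chromosome {proxy_chrom!r} not in genome")
    windows = predict.scan(model, genome, window=window, step=step,
                           chroms=[proxy_chrom])
    enhancers = predict.merge(windows)
    covered = sum(e.interval.length for e in enhancers)
    return covered / genome.length(proxy_chrom)


@dataclass
class SelectionReportRow:
    delta: float
    weights: WsvmWeights
    metrics: CvMetrics
    coverage: float
    excluded: bool
    selected: bool


@dataclass
class SelectionResult:
    config: PartitionConfig
    weights: WsvmWeights
    model: WsvmModel
    metrics: CvMetrics
    report: list[SelectionReportRow]


def _cv_counts(
    data: LabeledTraining,
    weights: WsvmWeights,
    folds: int,
    seed: int,
    tol: float,
) -> CvMetrics:
    """Stratified k-fold CV, pooling TP/FN/PP over the held-out folds."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fn = pp = 0
    for train_idx, test_idx in skf.split(data.X, data.set_labels):
        sub = LabeledTraining(
            X=data.X[train_idx],
            set_labels=data.set_labels[train_idx],
            y=data.y[train_idx],
            intervals=[data.intervals[i] for i in train_idx],
            k=data.k,
        )
        model = train(sub, weights, tol=tol)
        pred_pos = model.decision(data.X[test_idx]) > 0
        is_pos = data.y[test_idx] == 1
        tp += int(np.sum(pred_pos & is_pos))
        fn += int(np.sum(~pred_pos & is_pos))
        pp += int(np.sum(pred_pos))
    return CvMetrics(tp=tp, fn=fn, pp=pp)


def choose_best(candidates: list, tie_tol: float = 0.005):
    """Apply the selection rule to (delta, weights, metrics, ...) candidates.

    Candidates within *tie_tol* of the maximum F form the tie group; the
    highest-precision member wins; remaining ties go to the lexicographically
    smallest (delta, weights) grid point.  Empty input means every candidate
    was excluded by the coverage cap.
    """
    if not candidates:
        raise RuntimeError("no candidate model satisfies the coverage cap")
    best_f = max(c[2].f for c in candidates)
    group = [c for c in candidates if c[2].f >= best_f - tie_tol]
    group.sort(key=lambda c: (-c[2].precision, c[0], c[1].as_tuple()))
    return group[0]


def select_model(
    ranked,
    negatives_data: LabeledTraining,
    genome: Genome,
    weight_grid: Sequence[WsvmWeights],
    delta_grid: Sequence[float],
    ln_quantile: float,
    folds: int = 5,
    coverage_cap: float = 0.05,
    proxy_chrom: str | None = None,
    window: int = 2000,
    step: int = 500,
    seed: int = 0,
    tie_tol: float = 0.005,
    tol: float = 1e-4,
) -> SelectionResult:
    """Grid search over (delta, weights) with the F / precision / coverage rule.

    Parameters
    ----------
    ranked : list of RankedLmr (density quantiles already assigned).
    negatives_data : a LabeledTraining holding only the RN rows (its X/intervals
        are reused across grid points so negatives are encoded once).
    coverage_cap : candidates whose full-retrain proxy-chromosome coverage
        exceeds this fraction are discarded.

    Selection: among surviving candidates, those within *tie_tol* of the
    maximum pooled-CV F form the tie group; the highest-precision member wins,
    with remaining ties broken by the lexicographically smallest grid point.
    """
    if len(weight_grid) == 0 or len(delta_grid) == 0:
        raise ValueError("grids must be non-empty")
    if proxy_chrom is None:
        proxy_chrom = genome.chroms[0]

    rn_mask = negatives_data.set_labels == "RN"
    if not rn_mask.all():
        raise ValueError("negatives_data must contain only RN rows")

    report: list[SelectionReportRow] = []
    candidates = []  # (delta, weights, metrics, coverage, model)
    for delta in delta_grid:
        cfg = PartitionConfig(delta=delta, ln_quantile=ln_quantile)
        labels = partition(ranked, cfg)
        X = np.vstack([r.vector for r in ranked] + [negatives_data.X])
        set_labels = np.array(labels + ["RN"] * negatives_data.n)
        y = np.where(np.isin(set_labels, ("RP", "LP")), 1, -1)
        data = LabeledTraining(
            X=X, set_labels=set_labels, y=y,
            intervals=[r.interval for r in ranked] + negatives_data.intervals,
            k=negatives_data.k,
        )
        for weights in weight_grid:
            metrics = _cv_counts(data, weights, folds, seed, tol)
            full = train(data, weights, tol=tol)
            full.delta = delta
            cov = genomic_coverage(full, genome, proxy_chrom, window, step)
            metrics.coverage = cov
            excluded = cov > coverage_cap
            report.append(SelectionReportRow(
                delta=delta, weights=weights, metrics=metrics,
                coverage=cov, excluded=excluded, selected=False,
            ))
            if not excluded:
                candidates.append((delta, weights, metrics, cov, full))

    delta, weights, metrics, cov, model = choose_best(candidates, tie_tol)
    for row in report:
        if row.delta == delta and row.weights == weights:
            row.selected = True
    return SelectionResult(
        config=PartitionConfig(delta=delta, ln_quantile=ln_quantile),
        weights=weights,
        model=model,
        metrics=metrics,
        report=report,
    )


def save_model(model: WsvmModel, path: str | Path) -> None:
    """Serialize a model as plain text: header lines then one w entry per line."""
    with open(path, "w") as fh:
        fh.write("# lmrsvm linear model\n")
        fh.write(f"k\t{model.k}\n")
        fh.write(f"b\t{float(model.b)!r}\n")
        c = model.weights
        fh.write("weights\t" + "\t".join(
            repr(float(v)) for v in c.as_tuple()) + "\n")
        fh.write(f"delta\t{'' if model.delta is None else repr(float(model.delta))}\n")
        digest = hashlib.sha256(model.w.tobytes()).hexdigest()
        fh.write(f"w_sha256\t{digest}\n")
        fh.write(f"dim\t{model.w.size}\n")
        for v in model.w:
            fh.write(f"{float(v)!r}\n")


def load_model(path: str | Path) -> WsvmModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    header: dict[str, list[str]] = {}
    i = 0
    while i < len(lines) and "\t" in lines[i]:
        parts = lines[i].split("\t")
        header[parts[0]] = parts[1:]
        i += 1
    k = int(header["k"][0])
    b = float(header["b"][0])
    c = [float(v) for v in header["weights"]]
    delta = float(header["delta"][0]) if header["delta"][0] else None
    dim = int(header["dim"][0])
    w = np.array([float(v) for v in lines[i : i + dim]])
    if w.size != dim:
        raise ValueError("truncated model file")
    digest = hashlib.sha256(w.tobytes()).hexdigest()
    if digest != header["w_sha256"][0]:
        raise ValueError("model checksum mismatch")
    model = WsvmModel(w=w, b=b, weights=WsvmWeights(*c), k=k, delta=delta)
    return model
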