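"""Consensus effective connections via F-score ranking inside a LOOCV loop.

Each subject's directed connectivity matrix is flattened into the 52x51
ordered-pair feature vector (self-pairs excluded: the diagonal is identically
zero). Features are ranked by the two-class F-score

    F = [(m+ - m)^2 + (m- - m)^2] / [ s+^2 + s-^2 ]

where m is the grand mean, m+/m- the class means and s+^2 / s-^2 the sample
(n-1 denominator) within-class variances. Inside each leave-one-out fold the
ranking is computed on the training subjects only (no peeking at the held-out
subject); the consensus mask is the intersection over folds of each fold's
top-k feature set, i.e. the connections that survive feature selection no
matter which subject is left out. The selected count k is data-driven: the
smallest k maximising LOOCV accuracy of a linear SVM on the top-k features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import LeaveOneOut

from .classify import _svm_decision
from .errors import GroupSizeError, ShapeMismatchError
from .granger import EffConnMatrix


@dataclass(frozen=True)
class FeatureRanking:
    """Per-feature F-scores and the induced (stable) descending rank order."""

    feature_ids: tuple
    scores: np.ndarray
    order: np.ndarray  # feature indices, best first

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


@dataclass(frozen=True)
class ConsensusMask:
    """Binary R x R mask over ordered ROI pairs (diagonal always 0)."""

    mask: np.ndarray
    chosen_k: int
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ShapeMismatchError("mask must be square")
        if np.any(np.diag(m) != 0):
            raise ValueError("mask diagonal must be zero")
        object.__setattr__(self, "mask", m.astype(int))

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def feature_ids(n_rois: int) -> tuple[tuple[int, int], ...]:
    """Ordered (src, tgt) pairs, row-major, self-pairs excluded."""
    return tuple((i, j) for i in range(n_rois) for j in range(n_rois) if i != j)


def ecm_features(ecms: list[EffConnMatrix]) -> np.ndarray:
    """Stack per-subject matrices into an n_subjects x R(R-1) feature matrix."""
    if not ecms:
        raise GroupSizeError("no matrices given")
    R = ecms[0].n_rois
    ids = feature_ids(R)
    rows = np.empty((len(ecms), len(ids)))
    for s, ecm in enumerate(ecms):
        if ecm.n_rois != R:
            raise ShapeMismatchError("matrices differ in size")
        rows[s] = [ecm.values[i, j] for i, j in ids]
    return rows


def _class_split(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise GroupSizeError(f"exactly two classes required, got {classes.tolist()}")
    pos = labels == classes[0]
    neg = labels == classes[1]
    if pos.sum() < 2 or neg.sum() < 2:
        raise GroupSizeError("each class needs at least 2 samples")
    return pos, neg


def f_scores(
    feature_matrix: np.ndarray, labels: np.ndarray, ids: tuple | None = None
) -> FeatureRanking:
    """Two-class F-score per feature; ties in rank broken by feature id."""
    X = np.asarray(feature_matrix, dtype=float)
    pos, neg = _class_split(labels)
    grand = X.mean(axis=0)
    m_pos = X[pos].mean(axis=0)
    m_neg = X[neg].mean(axis=0)
    v_pos = X[pos].var(axis=0, ddof=1)
    v_neg = X[neg].var(axis=0, ddof=1)
    num = (m_pos - grand) ** 2 + (m_neg - grand) ** 2
    den = v_pos + v_neg
    scores = np.empty(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    degenerate = (den == 0) & (num > 0)
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) have zero pooled within-class "
            "variance; their F-score is +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        scores[degenerate] = np.inf
    # Stable sort on -score preserves feature-id order among ties.
    order = np.argsort(-scores, kind="stable")
    if ids is None:
        ids = tuple(range(X.shape[1]))
    return FeatureRanking(feature_ids=tuple(ids), scores=scores, order=order)


def _fold_rankings(X: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    loo = LeaveOneOut()
    return [f_scores(X[tr], labels[tr]).order for tr, _ in loo.split(X)]


def _fit_predict_one(X_tr, y_tr, x_te, C):
    """Linear-SVM prediction for one held-out sample (training-split scaling)."""
    classes = np.unique(y_tr)
    y01 = (y_tr == classes[1]).astype(float)
    mu = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0)
    sd[sd == 0] = 1.0
    d = _svm_decision((X_tr - mu) / sd, y01, (x_te - mu) / sd, C)
    return classes[1] if d > 0 else classes[0]


def accuracy_vs_k(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    k_grid: list[int] | tuple[int, ...],
    svm_C: float = 1.0,
    per_fold_ranking: bool = True,
) -> tuple[dict[int, float], int]:
    """LOOCV accuracy of a linear SVM on the top-k ranked features, per k.

    Rankings are recomputed inside each training fold (leakage-safe default);
    ``per_fold_ranking=False`` uses a single all-subject ranking for
    comparison. Returns (accuracy curve, best k); ties in the argmax go to the
    smallest k.
    """
    X = np.asarray(feature_matrix, dtype=float)
    labels = np.asarray(labels)
    _class_split(labels)
    k_grid = sorted(set(int(k) for k in k_grid))
    if k_grid[0] < 1 or k_grid[-1] > X.shape[1]:
        raise ValueError(f"k values must lie in [1, {X.shape[1]}]")
    loo = LeaveOneOut()
    folds = list(loo.split(X))
    if per_fold_ranking:
        rankings = [f_scores(X[tr], labels[tr]).order for tr, _ in folds]
    else:
        global_order = f_scores(X, labels).order
        rankings = [global_order for _ in folds]
    correct = {k: 0 for k in k_grid}
    for (tr, te), order in zip(folds, rankings):
        for k in k_grid:
            cols = order[:k]
            pred = _fit_predict_one(X[np.ix_(tr, cols)], labels[tr], X[te[0], cols], svm_C)
            correct[k] += int(pred == labels[te][0])
    n = X.shape[0]
    curve = {k: correct[k] / n for k in k_grid}
    best_k = min(curve, key=lambda k: (-curve[k], k))
    return curve, best_k


def consensus_features(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    chosen_k: int,
    per_fold_ranking: bool = True,
) -> np.ndarray:
    """Indices of features in every fold's top-``chosen_k`` training ranking."""
    X = np.asarray(feature_matrix, dtype=float)
    labels = np.asarray(labels)
    if not 1 <= chosen_k <= X.shape[1]:
        raise ValueError(f"chosen_k must lie in [1, {X.shape[1]}]")
    if per_fold_ranking:
        rankings = _fold_rankings(X, labels)
    else:
        rankings = [f_scores(X, labels).order]
    keep = set(rankings[0][:chosen_k].tolist())
    for order in rankings[1:]:
        keep &= set(order[:chosen_k].tolist())
    if not keep:
        warnings.warn("consensus feature set is empty", RuntimeWarning, stacklevel=2)
    return np.array(sorted(keep), dtype=int)


def consensus_mask(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    chosen_k: int,
    svm_C: float = 1.0,  # unused; kept for interface parity with accuracy_vs_k
    roi_labels: tuple[str, ...] | None = None,
    per_fold_ranking: bool = True,
) -> ConsensusMask:
    """Binary matrix mask of the consensus (fold-intersection) connections."""
    X = np.asarray(feature_matrix, dtype=float)
    n_features = X.shape[1]
    R = int(round((1 + np.sqrt(1 + 4 * n_features)) / 2))
    if R * (R - 1) != n_features:
        raise ShapeMismatchError(
            f"{n_features} features do not correspond to an R x (R-1) ordered-pair layout"
        )
    kept = consensus_features(X, labels, chosen_k, per_fold_ranking)
    ids = feature_ids(R)
    mask = np.zeros((R, R), dtype=int)
    for f in kept:
        i, j = ids[f]
        mask[i, j] = 1
    if roi_labels is None:
        roi_labels = tuple(f"roi{i}" for i in range(R))
    return ConsensusMask(mask=mask, chosen_k=chosen_k, roi_labels=roi_labels)


def apply_mask(ecm: EffConnMatrix, mask: ConsensusMask) -> EffConnMatrix:
    """Zero every connection outside the mask; flags the matrix as masked."""
    if mask.mask.shape != ecm.values.shape:
        raise ShapeMismatchError(
            f"mask shape {mask.mask.shape} does not match matrix {ecm.values.shape}"
        )
    return ecm.with_values(ecm.values * mask.mask, masked=True)
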