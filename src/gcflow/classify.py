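"""Linear-SVM leave-one-out classification with permutation significance.

AD is the positive class throughout: sensitivity is the fraction of patients
detected, specificity the fraction of controls cleared. Features are
standardised inside each training fold (mean/SD from the training split only)
before fitting a linear SVM at fixed C (default 1, the libsvm default). The
ROC area is computed from the held-out decision values via the Mann-Whitney
identity (ties counted half).

Significance uses label permutation with the full LOOCV re-run per
permutation and the add-one estimator

    p = (1 + #{permuted accuracy >= observed}) / (1 + n_perm),

which is never exactly zero; a result beating every permutation is reported
as p = 1/(1+n_perm) rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.svm import _libsvm as libsvm

from .errors import GroupSizeError, ShapeMismatchError

libsvm.set_verbosity_wrap(0)

POSITIVE_CLASS = "AD"
NEGATIVE_CLASS = "NC"


@dataclass(frozen=True)
class ClassificationResult:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    decision_values: np.ndarray
    predictions: np.ndarray
    permutation_p: float | None = None

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity", "auc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


def _encode(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - {POSITIVE_CLASS, NEGATIVE_CLASS}
    if bad:
        raise ValueError(f"labels must be 'AD'/'NC'; got extra {sorted(bad)}")
    return (labels == POSITIVE_CLASS).astype(int)


def _svm_decision(X_tr: np.ndarray, y_tr: np.ndarray, x_te: np.ndarray, C: float) -> float:
    """Linear C-SVC decision value for one query point (positive favours class 1).

    Goes through scikit-learn's libsvm binding directly: its label ordering is
    sorted, and for binary problems the raw libsvm decision is positive for
    class 0, hence the sign flip (matching ``SVC.decision_function``, which is
    asserted in the tests). The thin call path keeps the permutation test's
    tens of thousands of LOOCV refits affordable.
    """
    fit = libsvm.fit(
        np.ascontiguousarray(X_tr),
        np.ascontiguousarray(y_tr, dtype=np.float64),
        svm_type=0,
        kernel="linear",
        C=float(C),
    )
    support_vectors, dual_coef, intercept = fit[1], fit[3], fit[4]
    raw = x_te @ (dual_coef @ support_vectors).T + intercept
    return -float(np.ravel(raw)[0])


def loocv_svm(features: np.ndarray, labels: np.ndarray, C: float = 1.0) -> ClassificationResult:
    """Leave-one-out linear SVM; returns aggregate metrics and decision values.

    Features are standardised per fold with the training split's mean and SD
    (zero-variance columns pass through unscaled).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _encode(labels)
    n = X.shape[0]
    if y.size != n:
        raise ShapeMismatchError("features and labels disagree in length")
    if n < 4 or y.sum() < 2 or (n - y.sum()) < 2:
        raise GroupSizeError("need >= 4 subjects with >= 2 per class")
    preds = np.empty(n, dtype=int)
    decision = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        X_tr = X[mask]
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd[sd == 0] = 1.0
        d = _svm_decision((X_tr - mu) / sd, y[mask], (X[i] - mu) / sd, C)
        decision[i] = d
        preds[i] = int(d > 0)
        mask[i] = True
    tp = int(np.sum((preds == 1) & (y == 1)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    # accuracy = (sens * n_AD + spec * n_NC) / n, asserted as a sanity identity.
    n_ad, n_nc = tp + fn, tn + fp
    assert abs(accuracy - (sensitivity * n_ad + specificity * n_nc) / n) < 1e-12
    return ClassificationResult(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=roc_auc(decision, labels),
        decision_values=decision,
        predictions=preds,
    )


def roc_auc(decision_values: np.ndarray, labels: np.ndarray) -> float:
    """P(random AD decision value > random NC value), ties counted half."""
    d = np.asarray(decision_values, dtype=float)
    y = _encode(labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise GroupSizeError("both classes must be present for ROC analysis")
    from scipy.stats import rankdata

    ranks = rankdata(d)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def permutation_pvalue(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Add-one permutation p for LOOCV accuracy; returns (p, observed accuracy).

    Each permutation shuffles the class labels and re-runs the complete LOOCV.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    labels = np.asarray(labels)
    observed = loocv_svm(features, labels, C=C).accuracy
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        permuted = rng.permutation(labels)  # preserves class counts
        acc = loocv_svm(features, permuted, C=C).accuracy
        if acc >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(p), float(observed)


def classify_with_permutation(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClassificationResult:
    """LOOCV result with its permutation p attached."""
    result = loocv_svm(features, labels, C=C)
    p, _ = permutation_pvalue(features, labels, C=C, n_perm=n_perm, seed=seed)
    return replace(result, permutation_p=p)
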