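"""Bivariate Granger causality between ROI time series.

For an ordered pair (x -> y) and model order p, two autoregressions of y are
compared:

    restricted:  y_t ~ 1 + y_{t-1..t-p}
    full:        y_t ~ 1 + y_{t-1..t-p} + x_{t-1..t-p}

The Granger-causality magnitude is the Geweke log variance ratio

    F_{x->y} = ln( RSS_restricted / RSS_full )

(the 1/T_eff maximum-likelihood variance normalisation cancels in the ratio).
F is nonnegative in exact arithmetic because the restricted model is nested
in the full one; tiny negative values from finite precision are clipped to 0.
The statistic is in nats and is treated throughout as a directed connection
*strength*, so that sums of F over sets of ordered pairs (the information-flow
statistics) are well defined. A signed variant (F times the sign of the summed
x-lag coefficients) exists for sensitivity analyses only.

``pairwise_gc`` fills the full R x R matrix in one vectorised pass: all pair
regressions share the same lagged cross-moment matrices, so each pair costs
one small (2p+1) normal-equation solve rather than a fresh least-squares fit.
Columns are centred first (equivalent to including the intercept) to keep the
normal equations well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConstantSeriesError, ShapeMismatchError, ShortSeriesError
from .types import NetworkPartition, SubjectRecord

_RSS_FLOOR = 1e-300


@dataclass(frozen=True)
class EffConnMatrix:
    """Per-subject directed connectivity: ``values[i, j]`` = F_{i -> j}."""

    subject_id: str
    values: np.ndarray
    roi_labels: tuple[str, ...]
    var_order: int
    masked: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeMismatchError("connectivity values must be a square matrix")
        if v.shape[0] != len(self.roi_labels):
            raise ShapeMismatchError("matrix size does not match ROI label count")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if np.any(v < 0) or np.any(np.diag(v) != 0):
            raise ValueError("connectivity entries must be >= 0 with a zero diagonal")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, masked: bool | None = None) -> "EffConnMatrix":
        return replace(self, values=values, masked=self.masked if masked is None else masked)


def _lag_design(series: np.ndarray, order: int) -> np.ndarray:
    """Columns [s_{t-1}, ..., s_{t-p}] for t = p..T-1."""
    T = series.shape[0]
    return np.column_stack([series[order - k : T - k] for k in range(1, order + 1)])


def _ols_rss(design: np.ndarray, target: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ beta
    return float(resid @ resid)


def gc_pair(
    x_series: np.ndarray,
    y_series: np.ndarray,
    order: int = 1,
    signed: bool = False,
) -> float:
    """Granger-causality magnitude F_{x->y} for one ordered pair."""
    x = np.asarray(x_series, dtype=float).ravel()
    y = np.asarray(y_series, dtype=float).ravel()
    if x.shape != y.shape:
        raise ShapeMismatchError("x and y must have the same length")
    if order < 1:
        raise ValueError("order must be a positive integer")
    T = x.shape[0]
    if T < 10 * order:
        raise ShortSeriesError(f"series of length {T} too short for order {order} (need >= {10 * order})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError("constant input series")
    target = y[order:]
    ones = np.ones((T - order, 1))
    y_lags = _lag_design(y, order)
    x_lags = _lag_design(x, order)
    rss_restricted = _ols_rss(np.hstack([ones, y_lags]), target)
    full_design = np.hstack([ones, y_lags, x_lags])
    beta, *_ = np.linalg.lstsq(full_design, target, rcond=None)
    resid = target - full_design @ beta
    rss_full = float(resid @ resid)
    f = float(np.log(max(rss_restricted, _RSS_FLOOR) / max(rss_full, _RSS_FLOOR)))
    f = max(f, 0.0)
    if signed:
        sign = np.sign(np.sum(beta[1 + order :]))
        return f * (sign if sign != 0 else 1.0)
    return f


def _gc_block(
    data: np.ndarray,
    src_idx: np.ndarray,
    tgt_idx: np.ndarray,
    order: int,
) -> np.ndarray:
    """Vectorised F_{src -> tgt} for all (src, tgt) index pairs.

    Returns an array of shape (len(src_idx), len(tgt_idx)); entries where
    src == tgt are 0.
    """
    T, _ = data.shape
    p = order
    n_eff = T - p
    if n_eff < 2 * p + 2:
        raise ShortSeriesError(f"{T} samples too few for order {p}")
    Y = data[p:]
    lags = [data[p - k : T - k] for k in range(1, p + 1)]
    Yc = Y - Y.mean(axis=0)
    Lc = [L - L.mean(axis=0) for L in lags]
    # Shared cross-moment matrices: C[k][l][a, b] = <L_k[:,a], L_l[:,b]>
    C = [[Lc[k].T @ Lc[l] for l in range(p)] for k in range(p)]
    D = [Lc[k].T @ Yc for k in range(p)]
    yy = np.einsum("ij,ij->j", Yc, Yc)

    # Restricted model per target j: y_t ~ y-lags of j.
    tgt = np.asarray(tgt_idx, dtype=int)
    src = np.asarray(src_idx, dtype=int)
    nt, ns = len(tgt), len(src)
    A_r = np.empty((nt, p, p))
    b_r = np.empty((nt, p))
    for k in range(p):
        b_r[:, k] = D[k][tgt, tgt]
        for l in range(p):
            A_r[:, k, l] = C[k][l][tgt, tgt]
    beta_r = _solve_batch(A_r, b_r)
    rss_r = yy[tgt] - np.einsum("jk,jk->j", b_r, beta_r)

    # Full model per (i, j): columns [y-lags of j | x-lags of i].
    d = 2 * p
    A_f = np.empty((ns, nt, d, d))
    b_f = np.empty((ns, nt, d))
    for k in range(p):
        b_f[:, :, k] = D[k][tgt, tgt][np.newaxis, :]
        b_f[:, :, p + k] = D[k][np.ix_(src, tgt)]
        for l in range(p):
            A_f[:, :, k, l] = C[k][l][tgt, tgt][np.newaxis, :]
            A_f[:, :, k, p + l] = C[k][l][np.ix_(tgt, src)].T
            A_f[:, :, p + k, l] = C[k][l][np.ix_(src, tgt)]
            A_f[:, :, p + k, p + l] = C[k][l][src, src][:, np.newaxis]
    beta_f = _solve_batch(A_f.reshape(ns * nt, d, d), b_f.reshape(ns * nt, d))
    rss_f = yy[tgt][np.newaxis, :] - np.einsum(
        "ijk,ijk->ij", b_f, beta_f.reshape(ns, nt, d)
    )

    F = np.log(np.maximum(rss_r[np.newaxis, :], _RSS_FLOOR) / np.maximum(rss_f, _RSS_FLOOR))
    np.maximum(F, 0.0, out=F)
    same = src[:, None] == tgt[None, :]
    F[same] = 0.0
    return F


def _solve_batch(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, b[..., np.newaxis])[..., 0]
    except np.linalg.LinAlgError:
        # Singular designs (e.g. duplicated series): minimum-norm solution.
        return np.einsum("...ij,...j->...i", np.linalg.pinv(A), b)


def pairwise_gc(
    record: SubjectRecord,
    order: int = 1,
    partition: NetworkPartition | None = None,
) -> EffConnMatrix:
    """Directed R x R Granger matrix over every ordered ROI pair.

    When a partition is given its ROI labels are attached to the matrix (and
    the column count is checked); otherwise generic labels are used.
    """
    data = record.data
    T, R = data.shape
    if T < 10 * order:
        raise ShortSeriesError(
            f"subject {record.subject_id!r}: {T} timepoints too few for order {order}"
        )
    flat = np.ptp(data, axis=0) == 0
    if np.any(flat):
        idx = np.flatnonzero(flat)
        raise ConstantSeriesError(
            f"subject {record.subject_id!r}: constant series at column(s) {idx.tolist()}"
        )
    if partition is not None:
        record.check_against(partition)
        labels = tuple(partition.roi_labels)
    else:
        labels = tuple(f"roi{i}" for i in range(R))
    all_idx = np.arange(R)
    values = _gc_block(data, all_idx, all_idx, order)
    return EffConnMatrix(
        subject_id=record.subject_id,
        values=values,
        roi_labels=labels,
        var_order=order,
    )


def suggest_order(record: SubjectRecord, max_order: int = 6) -> int:
    """BIC-based VAR-order suggestion, averaged over univariate AR fits.

    A convenience for sensitivity analyses; the pipeline default stays at 1.
    """
    T = record.n_timepoints
    best_order, best_bic = 1, np.inf
    for p in range(1, max_order + 1):
        if T < 10 * p:
            break
        n_eff = T - p
        total = 0.0
        for col in record.data.T:
            target = col[p:]
            design = np.hstack([np.ones((n_eff, 1)), _lag_design(col, p)])
            rss = _ols_rss(design, target)
            sigma2 = max(rss / n_eff, _RSS_FLOOR)
            total += n_eff * np.log(sigma2) + (p + 1) * np.log(n_eff)
        if total < best_bic:
            best_bic, best_order = total, p
    return best_order
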