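"""ROI-level signal conditioning: confound regression and bandpass filtering.

The pipeline mirrors standard resting-state practice: nuisance signals
(motion parameters, linear drift, mean tissue signals) are removed from each
ROI series by ordinary least squares, then a temporal bandpass (default
0.01-0.08 Hz) suppresses slow drift and high-frequency noise. Filtering is
zero-phase (forward-backward Butterworth), which matters here because the
downstream Granger estimator is lag-based and one-pass filtering would
introduce phase delays.

The filter family and order are not dictated by the analysis model; a
second-order Butterworth applied with ``filtfilt`` is the package default and
both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from scipy import signal

from .errors import BandError, RankDeficientError, ShapeMismatchError
from .types import SubjectRecord


@dataclass(frozen=True)
class ConfoundSet:
    """Nuisance regressors for one subject (timepoints x k) with names."""

    regressors: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        reg = np.asarray(self.regressors, dtype=float)
        if reg.ndim != 2:
            raise ShapeMismatchError("confound regressors must be 2-D (timepoints x k)")
        if reg.shape[1] != len(self.names):
            raise ShapeMismatchError(
                f"{reg.shape[1]} regressor columns but {len(self.names)} names"
            )
        object.__setattr__(self, "regressors", reg)
        object.__setattr__(self, "names", tuple(self.names))


def _design_with_intercept(confounds: ConfoundSet | None, n_timepoints: int) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones((n_timepoints, 1))]
    names = ["intercept"]
    if confounds is not None:
        if confounds.regressors.shape[0] != n_timepoints:
            raise ShapeMismatchError(
                f"confounds have {confounds.regressors.shape[0]} timepoints, "
                f"series has {n_timepoints}"
            )
        cols.append(confounds.regressors)
        names.extend(confounds.names)
    return np.hstack(cols), names


def _check_full_rank(design: np.ndarray, names: Sequence[str]) -> None:
    # Pivoted QR exposes which columns are linearly dependent on earlier ones.
    _, r, piv = sla.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = design.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < design.shape[1]:
        offending = [names[j] for j in piv[rank:]]
        raise RankDeficientError(
            f"confound design is rank deficient; dependent column(s): {offending}"
        )


def regress_confounds(record: SubjectRecord, confounds: ConfoundSet | None = None) -> SubjectRecord:
    """Replace each ROI series by its OLS residual against [intercept | confounds].

    With no confounds this reduces to mean-centring. Residuals are orthogonal
    to every regressor by construction.
    """
    design, names = _design_with_intercept(confounds, record.n_timepoints)
    _check_full_rank(design, names)
    beta, *_ = np.linalg.lstsq(design, record.data, rcond=None)
    return record.with_data(record.data - design @ beta)


def bandpass_filter(
    record: SubjectRecord,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 2,
) -> SubjectRecord:
    """Zero-phase Butterworth bandpass, applied column-wise.

    Forward-backward filtering (``filtfilt``) preserves length and phase;
    edges are handled by reflective padding to tame transients on short
    (~190-sample) series.
    """
    nyquist = 1.0 / (2.0 * record.tr_seconds)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise BandError(
            f"band ({low_hz:g}, {high_hz:g}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist:g} Hz)"
        )
    b, a = signal.butter(order, [low_hz / nyquist, high_hz / nyquist], btype="bandpass")
    padlen = 3 * (max(len(a), len(b)) - 1)
    padlen = min(padlen, record.n_timepoints - 1)
    filtered = signal.filtfilt(b, a, record.data, axis=0, padtype="even", padlen=padlen)
    return record.with_data(filtered)


def condition(
    record: SubjectRecord,
    confounds: ConfoundSet | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    filter_order: int = 2,
) -> SubjectRecord:
    """Confound regression followed by bandpass filtering (in that order)."""
    return bandpass_filter(
        regress_confounds(record, confounds), low_hz, high_hz, order=filter_order
    )
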