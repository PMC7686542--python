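"""Core domain types: network partition, subject record, run configuration.

The pipeline operates on ROI-level BOLD time series. A :class:`NetworkPartition`
assigns each ROI to one of six resting-state subsystems (the three default-
network subsystems MTL, DM and Core, the two frontoparietal-control subsystems
FPCNA and FPCNB, and the dorsal attention network DAN). A
:class:`SubjectRecord` holds one subject's timepoints x ROIs matrix together
with its group label and sampling interval (TR).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .errors import (
    BandError,
    DuplicateROIError,
    PartitionError,
    ShapeMismatchError,
    UnknownNetworkError,
)

#: Canonical subsystem names, in display order.
NETWORKS: tuple[str, ...] = ("MTL", "DM", "Core", "FPCNA", "FPCNB", "DAN")

#: The three default-network (DN) subsystems.
DN_NETWORKS: tuple[str, ...] = ("MTL", "DM", "Core")

GROUPS: tuple[str, ...] = ("NC", "AD")


@dataclass(frozen=True)
class NetworkPartition:
    """Ordered ROI labels and their assignment to the six subsystems."""

    roi_labels: tuple[str, ...]
    network_of: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = tuple(self.roi_labels)
        object.__setattr__(self, "roi_labels", labels)
        object.__setattr__(self, "network_of", dict(self.network_of))
        seen: set[str] = set()
        for roi in labels:
            if roi in seen:
                raise DuplicateROIError(f"duplicate ROI label: {roi!r}")
            seen.add(roi)
        for roi in labels:
            net = self.network_of.get(roi)
            if net is None:
                raise PartitionError(f"ROI {roi!r} has no network assignment")
            if net not in NETWORKS:
                raise UnknownNetworkError(
                    f"ROI {roi!r} assigned to unknown network {net!r}; "
                    f"expected one of {NETWORKS}"
                )
        extra = set(self.network_of) - seen
        if extra:
            raise PartitionError(f"network map mentions unknown ROIs: {sorted(extra)}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @property
    def networks(self) -> tuple[str, ...]:
        """Subsystems present in this partition, in canonical order."""
        present = set(self.network_of.values())
        return tuple(n for n in NETWORKS if n in present)

    def rois_in(self, network: str) -> tuple[str, ...]:
        return tuple(r for r in self.roi_labels if self.network_of[r] == network)

    def indices_of(self, network: str) -> np.ndarray:
        """Column indices of the ROIs belonging to ``network``."""
        return np.array(
            [i for i, r in enumerate(self.roi_labels) if self.network_of[r] == network],
            dtype=int,
        )

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for net in self.networks:
            out[net] = len(self.rois_in(net))
        return out


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's ROI time-series matrix (timepoints x ROIs)."""

    subject_id: str
    group: str
    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ShapeMismatchError(
                f"subject {self.subject_id!r}: data must be 2-D, got {data.ndim}-D"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError(f"subject {self.subject_id!r}: data contains non-finite values")
        if self.group not in GROUPS:
            raise ValueError(
                f"subject {self.subject_id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if not self.tr_seconds > 0:
            raise ValueError(f"subject {self.subject_id!r}: tr_seconds must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "SubjectRecord":
        return replace(self, data=np.asarray(data, dtype=float))

    def check_against(self, partition: NetworkPartition) -> None:
        if self.n_rois != partition.n_rois:
            raise ShapeMismatchError(
                f"subject {self.subject_id!r}: {self.n_rois} ROI columns but the "
                f"partition defines {partition.n_rois}"
            )


@dataclass
class RunConfig:
    """Every pipeline constant, surfaced with its published default.

    var_order
        VAR model order used by the Granger estimator (lags).
    bandpass
        (low, high) passband in Hz for the temporal filter.
    window_seconds / step_timepoints
        Sliding-window length (seconds) and shift (samples) for the
        dynamic analysis: 60 s windows shifted by 3 timepoints (6 s at TR=2 s).
    alpha_primary
        Primary uncorrected significance level for group tests (0.01).
    fdr_q
        Benjamini-Hochberg level for the 30 inter-system tests (0.05).
    svm_C
        Linear-SVM regularisation constant (the libsvm default, 1).
    n_permutations
        Label permutations for classifier significance (1000).
    """

    var_order: int = 1
    bandpass: tuple[float, float] = (0.01, 0.08)
    window_seconds: float = 60.0
    step_timepoints: int = 3
    alpha_primary: float = 0.01
    fdr_q: float = 0.05
    svm_C: float = 1.0
    n_permutations: int = 1000
    rng_seed: int = 0
    k_grid: tuple[int, ...] | None = None
    mask_dynamic: bool = True
    use_masked_regional: bool = True
    filter_order: int = 2

    def validate(self, tr_seconds: float) -> None:
        low, high = self.bandpass
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0.0 < low < high < nyquist):
            raise BandError(
                f"bandpass {self.bandpass} must satisfy 0 < low < high < "
                f"Nyquist ({nyquist:g} Hz at TR={tr_seconds:g} s)"
            )
        if self.var_order < 1:
            raise ValueError("var_order must be a positive integer")
        window_samples = int(round(self.window_seconds / tr_seconds))
        if window_samples < self.var_order + 2:
            raise ValueError(
                f"window of {self.window_seconds:g} s is only {window_samples} samples "
                f"at TR={tr_seconds:g} s; need at least var_order+2 = {self.var_order + 2}"
            )
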