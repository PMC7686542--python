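"""Sliding-window inter-system IFS and temporal co-evolution.

The static analysis asks *how strongly* one subsystem drives another; the
dynamic analysis asks whether two such interactions *wax and wane together*.
Granger causality is re-estimated inside 60-second windows (30 samples at
TR = 2 s) shifted by 3 timepoints (6 s), giving one IFS time course per
ordered subsystem pair. Co-evolution is the Pearson correlation between two
such time courses, Fisher r-to-z transformed per subject, then tested with a
one-sample t against zero within each group and a pooled two-sample t across
groups.

Windows are half-open 0-based sample ranges [start, start + window). Within a
window the data are re-centred (implicitly, by the GC estimator) but not
re-filtered: filtering is a whole-series operation. Windowed pair IFS averages
the per-window GC over the pair's cross-network ROI pairs, restricted to the
consensus mask when one is supplied (consistent with the static analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .consensus import ConsensusMask
from .errors import ConstantSeriesError, GroupSizeError, WindowError
from .granger import _gc_block
from .ifs import CorrelationResult, GroupStats, group_compare
from .types import NetworkPartition, SubjectRecord


@dataclass(frozen=True)
class WindowSpec:
    """Half-open sliding windows with a constant step."""

    window_samples: int
    step_samples: int
    starts: tuple[int, ...]

    @property
    def n_windows(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class WindowedIFS:
    """One subject's windowed IFS time course for an ordered subsystem pair."""

    subject_id: str
    pair: tuple[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("windowed IFS contains non-finite values")
        object.__setattr__(self, "values", v)


def make_windows(
    T: int,
    tr_seconds: float,
    window_seconds: float = 60.0,
    step_samples: int = 3,
) -> WindowSpec:
    """Window starts 0, step, 2*step, ... while start + window <= T."""
    window_samples = int(round(window_seconds / tr_seconds))
    if window_samples < 2:
        raise WindowError(f"window of {window_seconds:g} s is under 2 samples at TR={tr_seconds:g} s")
    if step_samples < 1:
        raise WindowError("step must be a positive number of samples")
    if T < window_samples:
        raise WindowError(f"series of {T} samples shorter than the {window_samples}-sample window")
    starts = tuple(range(0, T - window_samples + 1, step_samples))
    return WindowSpec(window_samples=window_samples, step_samples=step_samples, starts=starts)


def windowed_intersystem_ifs(
    record: SubjectRecord,
    partition: NetworkPartition,
    pair: tuple[str, str],
    windows: WindowSpec,
    order: int = 1,
    mask: ConsensusMask | None = None,
) -> WindowedIFS:
    """Per-window mean GC over the pair's cross-network directed ROI pairs."""
    record.check_against(partition)
    src_net, tgt_net = pair
    src_idx = partition.indices_of(src_net)
    tgt_idx = partition.indices_of(tgt_net)
    if src_idx.size == 0 or tgt_idx.size == 0:
        raise WindowError(f"pair {pair} references an empty subsystem")
    if mask is not None:
        pair_mask = mask.mask[np.ix_(src_idx, tgt_idx)].astype(bool)
        if not pair_mask.any():
            raise WindowError(
                f"consensus mask selects no {src_net}->{tgt_net} connections"
            )
    else:
        pair_mask = np.ones((src_idx.size, tgt_idx.size), dtype=bool)
    if windows.window_samples < 10 * order:
        raise WindowError(
            f"{windows.window_samples}-sample window too short for GC order {order}"
        )
    values = np.empty(windows.n_windows)
    for w, start in enumerate(windows.starts):
        chunk = record.data[start : start + windows.window_samples]
        flat = np.ptp(chunk, axis=0) == 0
        if np.any(flat[src_idx]) or np.any(flat[tgt_idx]):
            raise ConstantSeriesError(
                f"constant series inside window {w} (start {start})"
            )
        F = _gc_block(chunk, src_idx, tgt_idx, order)
        values[w] = F[pair_mask].mean()
    return WindowedIFS(subject_id=record.subject_id, pair=(src_net, tgt_net), values=values)


def coevolution(series_a: np.ndarray, series_b: np.ndarray) -> CorrelationResult:
    """Pearson correlation between two windowed-IFS time courses."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size or a.size < 5:
        raise GroupSizeError("co-evolution needs equal-length series of >= 5 windows")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantSeriesError("zero-variance windowed-IFS series")
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(r=float(r), n=int(a.size), p=float(p))


@dataclass(frozen=True)
class CoevolutionTests:
    """One-sample t per group on Fisher-z co-evolution, plus the group contrast."""

    t_nc: float
    p_nc: float
    t_ad: float
    p_ad: float
    between: GroupStats
    mean_z_nc: float
    mean_z_ad: float


def _one_sample_t(z: np.ndarray) -> tuple[float, float]:
    if z.std(ddof=1) == 0.0:
        # degenerate: identical values; t is 0 at zero mean, infinite otherwise
        if z.mean() == 0.0:
            return 0.0, 1.0
        return float(np.sign(z.mean()) * np.inf), 0.0
    t, p = stats.ttest_1samp(z, 0.0)
    return float(t), float(p)


def coevolution_group_tests(z_values_nc: np.ndarray, z_values_ad: np.ndarray) -> CoevolutionTests:
    z_nc = np.asarray(z_values_nc, dtype=float)
    z_ad = np.asarray(z_values_ad, dtype=float)
    if z_nc.size < 2 or z_ad.size < 2:
        raise GroupSizeError("each group needs at least 2 subjects")
    t_nc, p_nc = _one_sample_t(z_nc)
    t_ad, p_ad = _one_sample_t(z_ad)
    between = group_compare(z_nc, z_ad)
    return CoevolutionTests(
        t_nc=float(t_nc), p_nc=float(p_nc), t_ad=float(t_ad), p_ad=float(p_ad),
        between=between, mean_z_nc=float(z_nc.mean()), mean_z_ad=float(z_ad.mean()),
    )
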