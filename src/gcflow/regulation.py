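"""The FPCNA regulatory-effect index.

The frontoparietal control network's A subsystem is hypothesised to mediate
default-network coupling. Its regulatory effect on a block of connections is
quantified as the drop in summed functional-connectivity strength once all
FPCNA signals are regressed out:

    full_strength    = sum over the block's unordered ROI pairs of atanh(r)
    partial_strength = the same after residualising every block ROI's series
                       against [intercept | all FPCNA ROI series]
    regulatory_effect = full_strength - partial_strength

Residualising against the full FPCNA signal set is algebraically equivalent
to the block partial correlation controlling for the FPCNA. Fisher's z is
applied per pair before summing. The five canonical blocks are the three
within-DN-subsystem blocks and the Core-DAN and DM-DAN cross blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .errors import ConstantSeriesError, GroupSizeError
from .ifs import GroupStats, group_compare
from .types import NetworkPartition, SubjectRecord

#: block id -> networks involved (one network = within block, two = cross block)
DEFAULT_BLOCKS: dict[str, tuple[str, ...]] = {
    "within-Core": ("Core",),
    "within-MTL": ("MTL",),
    "within-DM": ("DM",),
    "Core-DAN": ("Core", "DAN"),
    "DM-DAN": ("DM", "DAN"),
}


@dataclass(frozen=True)
class FcStrength:
    """Per-subject full/partial connectivity strength for one block."""

    subject_id: str
    block: str
    full_strength: float
    partial_strength: float

    @property
    def regulatory_effect(self) -> float:
        return self.full_strength - self.partial_strength


def _block_pairs(partition: NetworkPartition, block: str, blocks: dict[str, tuple[str, ...]]) -> list[tuple[int, int]]:
    nets = blocks[block]
    if len(nets) == 1:
        idx = partition.indices_of(nets[0])
        return [(int(idx[a]), int(idx[b])) for a in range(len(idx)) for b in range(a + 1, len(idx))]
    ia, ib = partition.indices_of(nets[0]), partition.indices_of(nets[1])
    return [(int(a), int(b)) for a in ia for b in ib]


def _strength(data: np.ndarray, pairs: list[tuple[int, int]]) -> float:
    cols = sorted({i for p in pairs for i in p})
    sub = data[:, cols]
    if np.any(np.ptp(sub, axis=0) == 0):
        raise ConstantSeriesError("constant ROI series in correlation block")
    pos = {c: k for k, c in enumerate(cols)}
    corr = np.corrcoef(sub, rowvar=False)
    total = 0.0
    for a, b in pairs:
        total += float(np.arctanh(np.clip(corr[pos[a], pos[b]], -1.0, 1.0)))
    return total


def full_fc_strength(
    record: SubjectRecord,
    partition: NetworkPartition,
    block: str,
    blocks: dict[str, tuple[str, ...]] | None = None,
) -> float:
    """Summed Fisher-z Pearson correlation over the block's unordered pairs."""
    blocks = blocks or DEFAULT_BLOCKS
    record.check_against(partition)
    return _strength(record.data, _block_pairs(partition, block, blocks))


def _residualise(data: np.ndarray, regressor_cols: np.ndarray, target_cols: list[int]) -> np.ndarray:
    T = data.shape[0]
    X = np.column_stack([np.ones(T), data[:, regressor_cols]])
    # Drop linearly dependent regressor columns (pivoted QR), with a warning.
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = T * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - rank} linearly dependent removed-network column(s)",
            RuntimeWarning,
            stacklevel=3,
        )
        X = X[:, np.sort(piv[:rank])]
    beta, *_ = np.linalg.lstsq(X, data[:, target_cols], rcond=None)
    return data[:, target_cols] - X @ beta


def partial_fc_strength(
    record: SubjectRecord,
    partition: NetworkPartition,
    block: str,
    removed_network: str = "FPCNA",
    blocks: dict[str, tuple[str, ...]] | None = None,
) -> float:
    """Block strength after regressing out every signal of ``removed_network``.

    With an empty removed network the design reduces to the intercept, so the
    partial strength equals the full strength exactly (correlations are
    invariant to mean-centring).
    """
    blocks = blocks or DEFAULT_BLOCKS
    record.check_against(partition)
    removed = partition.indices_of(removed_network) if removed_network in partition.networks else np.array([], dtype=int)
    if removed.size >= record.n_timepoints - 2:
        raise GroupSizeError(
            f"{removed.size} removed-network regressors for only {record.n_timepoints} timepoints"
        )
    pairs = _block_pairs(partition, block, blocks)
    cols = sorted({i for p in pairs for i in p})
    resid = _residualise(record.data, removed, cols)
    remap = {c: k for k, c in enumerate(cols)}
    return _strength(resid, [(remap[a], remap[b]) for a, b in pairs])


def regulation_table(
    records: list[SubjectRecord],
    partition: NetworkPartition,
    blocks: dict[str, tuple[str, ...]] | None = None,
    removed_network: str = "FPCNA",
) -> pd.DataFrame:
    """subject x block table of full, partial and regulatory-effect values."""
    blocks = blocks or DEFAULT_BLOCKS
    rows = []
    for rec in records:
        for block in blocks:
            full = full_fc_strength(rec, partition, block, blocks)
            part = partial_fc_strength(rec, partition, block, removed_network, blocks)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "block": block,
                    "full": full,
                    "partial": part,
                    "effect": full - part,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegulationTests:
    """Per-block paired tests (full vs partial) and the group contrast on effect."""

    block: str
    paired_t_nc: float
    paired_p_nc: float
    paired_t_ad: float
    paired_p_ad: float
    between: GroupStats


def regulation_tests(table: pd.DataFrame) -> list[RegulationTests]:
    """Within each group a paired t (full vs partial); across groups a pooled
    two-sample t on the regulatory effect, per block."""
    out = []
    for block, sub in table.groupby("block", sort=False):
        by_group = {}
        for grp in ("NC", "AD"):
            g = sub[sub["group"] == grp]
            if len(g) < 2:
                raise GroupSizeError(f"group {grp!r} has fewer than 2 subjects for block {block!r}")
            t, p = stats.ttest_rel(g["full"], g["partial"])
            by_group[grp] = (float(t), float(p), g["effect"].to_numpy())
        between = group_compare(by_group["NC"][2], by_group["AD"][2])
        out.append(
            RegulationTests(
                block=block,
                paired_t_nc=by_group["NC"][0], paired_p_nc=by_group["NC"][1],
                paired_t_ad=by_group["AD"][0], paired_p_ad=by_group["AD"][1],
                between=between,
            )
        )
    return out
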