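"""Information-flow-strength (IFS) statistics and group-level tests.

Regional IFS summarises, for each ROI, the summed Granger-causal strength it
exchanges with the rest of the brain, split by direction (in/out) and by
whether the partner ROIs share its subsystem (intra) or not (inter):

    intra_in(r)  = sum_{s in N(r), s != r} F_{s->r}
    intra_out(r) = sum_{s in N(r), s != r} F_{r->s}
    inter_in(r)  = sum_{s not in N(r)}     F_{s->r}
    inter_out(r) = sum_{s not in N(r)}     F_{r->s}

plus the four sums intra_in_out, inter_in_out, intra_inter_in and
intra_inter_out. Inter-system IFS sums F over every directed ROI pair running
from one subsystem into another (30 ordered pairs for six subsystems).

Because every directed edge is counted exactly once as an inflow and once as
an outflow, the sums obey exact conservation laws (per-network intra-in total
equals intra-out total; global inter-in = inter-out = total inter-system
flow), which the tests assert bitwise.

Group comparisons use the pooled-variance (Student) two-sample t-test
(df = n1+n2-2, matching the published df = 49 for 27 vs 24), BH-FDR over the
30 inter-system tests, Pearson correlations with Fisher's r-to-z transform,
and the classical two-sample Z-test on independent correlations,

    Z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import GroupSizeError, ShapeMismatchError
from .granger import EffConnMatrix
from .types import NetworkPartition

REGIONAL_INDICATORS: tuple[str, ...] = (
    "intra_in",
    "intra_out",
    "intra_in_out",
    "inter_in",
    "inter_out",
    "inter_in_out",
    "intra_inter_in",
    "intra_inter_out",
)


@dataclass(frozen=True)
class GroupStats:
    """Pooled-variance two-sample t-test result."""

    t: float
    df: int
    p: float
    mean1: float
    mean2: float
    infinite: bool = False

    @property
    def direction(self) -> str:
        if self.mean1 == self.mean2:
            return "equal"
        return "group1>group2" if self.mean1 > self.mean2 else "group1<group2"


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its Fisher z transform."""

    r: float
    n: int
    p: float

    @property
    def fisher_z(self) -> float:
        return float(np.arctanh(self.r))


def _check_labels(ecm: EffConnMatrix, partition: NetworkPartition) -> None:
    if ecm.n_rois != partition.n_rois:
        raise ShapeMismatchError(
            f"matrix has {ecm.n_rois} ROIs, partition {partition.n_rois}"
        )
    generic = all(l.startswith("roi") for l in ecm.roi_labels)
    if not generic and tuple(ecm.roi_labels) != tuple(partition.roi_labels):
        raise ShapeMismatchError("matrix ROI labels do not match the partition")


def regional_ifs(ecm: EffConnMatrix, partition: NetworkPartition) -> pd.DataFrame:
    """The eight per-ROI indicators for one subject's matrix."""
    _check_labels(ecm, partition)
    F = ecm.values
    R = ecm.n_rois
    net_of = np.array([partition.network_of[r] for r in partition.roi_labels])
    same = net_of[:, None] == net_of[None, :]
    np.fill_diagonal(same, False)
    other = ~(net_of[:, None] == net_of[None, :])
    # inflow to r: column r of F; outflow from r: row r.
    intra_in = np.sum(F * same, axis=0)
    intra_out = np.sum(F * same, axis=1)
    inter_in = np.sum(F * other, axis=0)
    inter_out = np.sum(F * other, axis=1)
    df = pd.DataFrame(
        {
            "subject_id": ecm.subject_id,
            "roi": list(partition.roi_labels),
            "network": net_of,
            "intra_in": intra_in,
            "intra_out": intra_out,
            "intra_in_out": intra_in + intra_out,
            "inter_in": inter_in,
            "inter_out": inter_out,
            "inter_in_out": inter_in + inter_out,
            "intra_inter_in": intra_in + inter_in,
            "intra_inter_out": intra_out + inter_out,
        }
    )
    return df


def regional_ifs_table(ecms: list[EffConnMatrix], partition: NetworkPartition, groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Stacked regional IFS for a cohort, with an optional group column."""
    frames = [regional_ifs(e, partition) for e in ecms]
    table = pd.concat(frames, ignore_index=True)
    if groups is not None:
        table.insert(1, "group", table["subject_id"].map(groups))
    return table


def intersystem_ifs(ecm: EffConnMatrix, partition: NetworkPartition) -> dict[tuple[str, str], float]:
    """Summed flow for every ordered pair of distinct subsystems."""
    _check_labels(ecm, partition)
    F = ecm.values
    nets = partition.networks
    idx = {n: partition.indices_of(n) for n in nets}
    out: dict[tuple[str, str], float] = {}
    for src in nets:
        for tgt in nets:
            if src == tgt:
                continue
            out[(src, tgt)] = float(F[np.ix_(idx[src], idx[tgt])].sum())
    return out


def intersystem_ifs_table(ecms: list[EffConnMatrix], partition: NetworkPartition, groups: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for ecm in ecms:
        vals = intersystem_ifs(ecm, partition)
        for (src, tgt), v in vals.items():
            rows.append({"subject_id": ecm.subject_id, "source": src, "target": tgt, "ifs": v})
    table = pd.DataFrame(rows)
    if groups is not None:
        table.insert(1, "group", table["subject_id"].map(groups))
    return table


def group_compare(values_1: np.ndarray, values_2: np.ndarray) -> GroupStats:
    """Pooled-variance (Student) two-sample t-test, two-sided."""
    a = np.asarray(values_1, dtype=float)
    b = np.asarray(values_2, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise GroupSizeError("each group needs at least 2 values")
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return GroupStats(t=0.0, df=df, p=1.0, mean1=float(a.mean()), mean2=float(b.mean()))
        return GroupStats(
            t=float(np.sign(diff) * np.inf), df=df, p=0.0,
            mean1=float(a.mean()), mean2=float(b.mean()), infinite=True,
        )
    t = diff / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupStats(t=float(t), df=df, p=float(p), mean1=float(a.mean()), mean2=float(b.mean()))


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: significance mask and adaptive p cutoff.

    The cutoff is the largest p-value passing the step-up rule (0.0 when
    nothing passes); thresholding at the cutoff reproduces the mask.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold


def intersystem_group_tests(table: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Per ordered subsystem pair: NC-vs-AD pooled t, p, and BH-FDR flag."""
    rows = []
    for (src, tgt), sub in table.groupby(["source", "target"], sort=True):
        nc = sub.loc[sub["group"] == "NC", "ifs"].to_numpy()
        ad = sub.loc[sub["group"] == "AD", "ifs"].to_numpy()
        gs = group_compare(nc, ad)
        rows.append(
            {
                "source": src, "target": tgt, "t": gs.t, "df": gs.df, "p": gs.p,
                "mean_nc": gs.mean1, "mean_ad": gs.mean2, "direction": gs.direction,
            }
        )
    out = pd.DataFrame(rows)
    reject, threshold = bh_fdr(out["p"].to_numpy(), q=q)
    out["significant_fdr"] = reject
    out.attrs["fdr_threshold"] = threshold
    return out


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise GroupSizeError("correlation needs two equal-length vectors of n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise GroupSizeError("zero-variance input to correlation")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=int(x.size), p=float(p))


def intra_inter_correlation(
    regional_table: pd.DataFrame,
    roi_subset: list[str],
    group: str,
) -> dict[str, CorrelationResult]:
    """Per ROI: Pearson r across a group's subjects between the intra-in+out
    and inter-in+out indicators (uncorrected p, as in the source analysis)."""
    out: dict[str, CorrelationResult] = {}
    sub = regional_table[regional_table["group"] == group]
    for roi in roi_subset:
        rows = sub[sub["roi"] == roi]
        if len(rows) < 3:
            raise GroupSizeError(f"fewer than 3 subjects for ROI {roi!r} in group {group!r}")
        out[roi] = pearson(rows["intra_in_out"].to_numpy(), rows["inter_in_out"].to_numpy())
    return out


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher Z-test for two independent correlations; returns (Z, two-sided p)."""
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 for the Fisher Z comparison")
    if n1 < 4 or n2 < 4:
        raise GroupSizeError("need n >= 4 in each group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
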