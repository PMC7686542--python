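"""End-to-end orchestration: conditioned series -> report tables.

``run_pipeline`` chains the whole analysis on an in-memory cohort and writes
every result as a TSV table:

1. signal conditioning (confound regression + 0.01-0.08 Hz bandpass);
2. per-subject directed Granger matrices;
3. consensus-edge selection (F-score ranking in a LOOCV loop, data-driven k)
   and masking;
4. regional IFS with per-ROI group t-tests;
5. inter-system IFS with pooled t-tests and BH-FDR, plus the forward/feedback
   coupling correlations compared across groups by Fisher Z;
6. windowed co-evolution of the FPCNA->Core/Core->DAN and FPCNA->DM/DM->DAN
   interaction pairs;
7. the FPCNA regulatory-effect tests;
8. single-indicator SVM classification with permutation significance.

Runs are deterministic (byte-identical tables) for a fixed ``rng_seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import conditioning, consensus, dynamics, granger, ifs, regulation
from .classify import classify_with_permutation
from .consensus import ConsensusMask
from .errors import GroupSizeError, WindowError
from .io import FLOAT_FORMAT, write_matrix
from .types import DN_NETWORKS, NetworkPartition, RunConfig, SubjectRecord

log = logging.getLogger("gcflow")

#: co-evolution interaction pairs examined by default
COEVOLUTION_PAIRS: tuple[tuple[tuple[str, str], tuple[str, str]], ...] = (
    (("FPCNA", "Core"), ("Core", "DAN")),
    (("FPCNA", "DM"), ("DM", "DAN")),
)

DEFAULT_K_GRID = (10, 25, 50, 100, 200, 400, 800, 1320, 2000, 2652)


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    mask: ConsensusMask
    best_k: int
    accuracy_curve: dict[int, float]
    out_dir: Path


def _check_groups(subjects: list[SubjectRecord]) -> dict[str, str]:
    groups = {s.subject_id: s.group for s in subjects}
    n_nc = sum(1 for g in groups.values() if g == "NC")
    n_ad = sum(1 for g in groups.values() if g == "AD")
    if n_nc < 2 or n_ad < 2:
        raise GroupSizeError(
            f"need at least 2 subjects per group, got NC={n_nc}, AD={n_ad}"
        )
    return groups


def _regional_group_tests(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    rows = []
    for (roi, network), sub in table.groupby(["roi", "network"], sort=False):
        for ind in ifs.REGIONAL_INDICATORS:
            nc = sub.loc[sub["group"] == "NC", ind].to_numpy()
            ad = sub.loc[sub["group"] == "AD", ind].to_numpy()
            gs = ifs.group_compare(nc, ad)
            rows.append(
                {
                    "roi": roi, "network": network, "indicator": ind,
                    "t": gs.t, "df": gs.df, "p": gs.p,
                    "mean_nc": gs.mean1, "mean_ad": gs.mean2,
                    "significant": bool(gs.p < alpha),
                }
            )
    return pd.DataFrame(rows)


def _coupling_correlation_tests(inter_table: pd.DataFrame) -> pd.DataFrame:
    """FPCNA<->DN forward/feedback coupling, correlated per group, Z-compared."""
    rows = []
    for dn in DN_NETWORKS:
        res = {}
        for grp in ("NC", "AD"):
            sub = inter_table[inter_table["group"] == grp]
            fwd = (
                sub[(sub["source"] == "FPCNA") & (sub["target"] == dn)]
                .set_index("subject_id")["ifs"]
            )
            bwd = (
                sub[(sub["source"] == dn) & (sub["target"] == "FPCNA")]
                .set_index("subject_id")["ifs"]
            )
            bwd = bwd.loc[fwd.index]
            try:
                res[grp] = ifs.pearson(fwd.to_numpy(), bwd.to_numpy())
            except GroupSizeError:
                # degenerate on tiny/masked-out cohorts: no usable variation
                res[grp] = ifs.CorrelationResult(r=float("nan"), n=len(fwd), p=float("nan"))
        usable = all(
            np.isfinite(res[g].r) and abs(res[g].r) < 1.0 and res[g].n >= 4
            for g in ("NC", "AD")
        )
        if usable:
            z, p = ifs.compare_correlations(
                res["NC"].r, res["NC"].n, res["AD"].r, res["AD"].n
            )
        else:
            z, p = float("nan"), float("nan")
        rows.append(
            {
                "pair": f"FPCNA<->{dn}",
                "r_nc": res["NC"].r, "p_nc": res["NC"].p,
                "r_ad": res["AD"].r, "p_ad": res["AD"].p,
                "z": z, "p_z": p,
            }
        )
    return pd.DataFrame(rows)


def _coevolution_table(
    conditioned: list[SubjectRecord],
    partition: NetworkPartition,
    config: RunConfig,
    mask: ConsensusMask | None,
) -> pd.DataFrame:
    rows = []
    T = conditioned[0].n_timepoints
    windows = dynamics.make_windows(
        T, conditioned[0].tr_seconds, config.window_seconds, config.step_timepoints
    )
    for pair_a, pair_b in COEVOLUTION_PAIRS:
        z_by_group: dict[str, list[float]] = {"NC": [], "AD": []}
        for rec in conditioned:
            use_mask = mask if config.mask_dynamic else None
            try:
                wa = dynamics.windowed_intersystem_ifs(
                    rec, partition, pair_a, windows, config.var_order, use_mask
                )
                wb = dynamics.windowed_intersystem_ifs(
                    rec, partition, pair_b, windows, config.var_order, use_mask
                )
            except WindowError:
                # consensus mask may select no connection for a pair on small
                # cohorts; fall back to all cross-network pairs
                wa = dynamics.windowed_intersystem_ifs(
                    rec, partition, pair_a, windows, config.var_order, None
                )
                wb = dynamics.windowed_intersystem_ifs(
                    rec, partition, pair_b, windows, config.var_order, None
                )
            z_by_group[rec.group].append(
                dynamics.coevolution(wa.values, wb.values).fisher_z
            )
        tests = dynamics.coevolution_group_tests(
            np.array(z_by_group["NC"]), np.array(z_by_group["AD"])
        )
        rows.append(
            {
                "pair_a": "->".join(pair_a), "pair_b": "->".join(pair_b),
                "mean_z_nc": tests.mean_z_nc, "t_nc": tests.t_nc, "p_nc": tests.p_nc,
                "mean_z_ad": tests.mean_z_ad, "t_ad": tests.t_ad, "p_ad": tests.p_ad,
                "t_between": tests.between.t, "df_between": tests.between.df,
                "p_between": tests.between.p,
            }
        )
    return pd.DataFrame(rows)


def _classification_summary(
    regional_table: pd.DataFrame,
    regional_tests: pd.DataFrame,
    groups: dict[str, str],
    config: RunConfig,
    n_features: int = 3,
) -> pd.DataFrame:
    finite = regional_tests[np.isfinite(regional_tests["t"])]
    top = finite.reindex(finite["t"].abs().sort_values(ascending=False).index).head(n_features)
    subjects = sorted(groups)
    labels = np.array([groups[s] for s in subjects])
    rows = []
    for rank, row in enumerate(top.itertuples(index=False)):
        feat = (
            regional_table[regional_table["roi"] == row.roi]
            .set_index("subject_id")
            .loc[subjects, row.indicator]
            .to_numpy()
        )
        res = classify_with_permutation(
            feat[:, None], labels, C=config.svm_C,
            n_perm=config.n_permutations, seed=config.rng_seed + rank,
        )
        rows.append(
            {
                "feature": f"{row.indicator} of {row.roi}",
                "accuracy": res.accuracy, "sensitivity": res.sensitivity,
                "specificity": res.specificity, "auc": res.auc,
                "permutation_p": res.permutation_p,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    subjects: list[SubjectRecord],
    partition: NetworkPartition,
    out_dir: str | Path,
) -> PipelineResult:
    """Run the full analysis and write the report bundle under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = _check_groups(subjects)
    tr = subjects[0].tr_seconds
    config.validate(tr)
    log.info("pipeline: %d subjects, %d ROIs", len(subjects), partition.n_rois)

    conditioned = [
        conditioning.condition(
            s, low_hz=config.bandpass[0], high_hz=config.bandpass[1],
            filter_order=config.filter_order,
        )
        for s in subjects
    ]
    log.info("conditioned series: %s", conditioned[0].data.shape)

    ecms = [granger.pairwise_gc(s, config.var_order, partition) for s in conditioned]
    ecm_dir = out_dir / "ecm"
    ecm_dir.mkdir(exist_ok=True)
    for e in ecms:
        write_matrix(e.values, e.roi_labels, ecm_dir / f"{e.subject_id}.tsv")
    log.info("granger matrices: %d x (%d, %d)", len(ecms), ecms[0].n_rois, ecms[0].n_rois)

    features = consensus.ecm_features(ecms)
    labels = np.array([e.subject_id for e in ecms])
    labels = np.array([groups[s] for s in labels])
    k_grid = config.k_grid or tuple(k for k in DEFAULT_K_GRID if k <= features.shape[1])
    curve, best_k = consensus.accuracy_vs_k(features, labels, k_grid, config.svm_C)
    mask = consensus.consensus_mask(
        features, labels, best_k, config.svm_C, roi_labels=tuple(partition.roi_labels)
    )
    masked = [consensus.apply_mask(e, mask) for e in ecms]
    write_matrix(mask.mask, partition.roi_labels, out_dir / "consensus_mask.tsv")
    log.info("consensus: k=%d -> %d edges", best_k, mask.n_selected)

    used = masked if config.use_masked_regional else ecms
    regional = ifs.regional_ifs_table(used, partition, groups)
    regional_tests = _regional_group_tests(regional, config.alpha_primary)
    inter = ifs.intersystem_ifs_table(used, partition, groups)
    inter_tests = ifs.intersystem_group_tests(inter, q=config.fdr_q)
    corr_tests = _coupling_correlation_tests(inter)
    coev = _coevolution_table(conditioned, partition, config, mask)
    reg_table = regulation.regulation_table(conditioned, partition)
    reg_tests = pd.DataFrame(
        [
            {
                "block": r.block,
                "paired_t_nc": r.paired_t_nc, "paired_p_nc": r.paired_p_nc,
                "paired_t_ad": r.paired_t_ad, "paired_p_ad": r.paired_p_ad,
                "t_between": r.between.t, "df_between": r.between.df,
                "p_between": r.between.p,
            }
            for r in regulation.regulation_tests(reg_table)
        ]
    )
    clf = _classification_summary(regional, regional_tests, groups, config)

    tables = {
        "regional_ifs": regional,
        "regional_tests": regional_tests,
        "intersystem_tests": inter_tests,
        "coupling_correlations": corr_tests,
        "coevolution_tests": coev,
        "regulation_tests": reg_tests,
        "classification_summary": clf,
    }
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    log.info("wrote %d tables to %s", len(tables) + 2, out_dir)
    return PipelineResult(
        tables=tables, mask=mask, best_k=best_k, accuracy_curve=curve, out_dir=out_dir
    )
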