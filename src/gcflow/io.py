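"""Reading and writing the pipeline's on-disk artifacts.

Everything is delimited text (TSV with header rows): per-subject time-series
tables, the ROI-to-network partition, connectivity matrices, cohort manifests
and YAML run configuration. Files are written with a fixed float format so a
run with the same seed is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DuplicateROIError,
    MissingROIError,
    NonNumericError,
    PartitionError,
    ShapeMismatchError,
    UnknownNetworkError,
)
from .types import NETWORKS, NetworkPartition, RunConfig, SubjectRecord

FLOAT_FORMAT = "%.10g"


def read_partition(path: str | Path) -> NetworkPartition:
    """Read a two-column (roi, network) TSV into a :class:`NetworkPartition`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise PartitionError(f"{path}: expected two columns (roi, network)")
    rois = df.iloc[:, 0].tolist()
    nets = df.iloc[:, 1].tolist()
    dupes = [r for r in set(rois) if rois.count(r) > 1]
    if dupes:
        raise DuplicateROIError(f"{path}: ROI listed more than once: {sorted(dupes)}")
    bad = sorted({n for n in nets if n not in NETWORKS})
    if bad:
        raise UnknownNetworkError(f"{path}: unknown network token(s): {bad}")
    return NetworkPartition(tuple(rois), dict(zip(rois, nets)))


def default_partition() -> NetworkPartition:
    """The packaged 52-ROI / six-subsystem partition (6/9/9/11/9/8)."""
    with resources.as_file(
        resources.files("gcflow").joinpath("data/default_partition.tsv")
    ) as p:
        return read_partition(p)


def read_timeseries_table(
    path: str | Path,
    partition: NetworkPartition,
    subject_id: str | None = None,
    group: str = "NC",
    tr_seconds: float = 2.0,
) -> SubjectRecord:
    """Read one subject's timepoints x ROIs table, reordered to the partition.

    The header row must contain every ROI label in the partition (any column
    order); extra columns are ignored.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise DuplicateROIError(f"{path}: duplicate column label(s): {dupes}")
    missing = [r for r in partition.roi_labels if r not in header]
    if missing:
        raise MissingROIError(f"{path}: missing ROI column(s): {missing}")
    df = pd.read_csv(path, sep="\t")
    sub = df[list(partition.roi_labels)]
    try:
        data = sub.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise NonNumericError(f"{path}: non-numeric cell in time-series table: {exc}") from exc
    if not np.all(np.isfinite(data)):
        bad_cols = [c for c in partition.roi_labels if not np.all(np.isfinite(sub[c].to_numpy(float)))]
        raise NonNumericError(f"{path}: non-finite value(s) in column(s): {bad_cols}")
    return SubjectRecord(
        subject_id=subject_id or path.stem,
        group=group,
        data=data,
        tr_seconds=tr_seconds,
    )


def write_timeseries_table(record: SubjectRecord, partition: NetworkPartition, path: str | Path) -> None:
    record.check_against(partition)
    df = pd.DataFrame(record.data, columns=list(partition.roi_labels))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_matrix(values: np.ndarray, roi_labels: Sequence[str], path: str | Path) -> None:
    """Write an R x R matrix as TSV with ROI labels on both axes."""
    df = pd.DataFrame(values, index=list(roi_labels), columns=list(roi_labels))
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="roi")


def read_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a labelled square matrix; validates that row labels equal columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ShapeMismatchError(f"{path}: row labels do not match column labels")
    return df.to_numpy(dtype=float), tuple(df.columns)


def write_cohort(
    records: Iterable[SubjectRecord],
    partition: NetworkPartition,
    out_dir: str | Path,
) -> Path:
    """Write one TSV per subject plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.subject_id}.tsv"
        write_timeseries_table(rec, partition, out_dir / fname)
        rows.append(
            {"subject_id": rec.subject_id, "group": rec.group, "path": fname, "tr_seconds": rec.tr_seconds}
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(manifest_path: str | Path, partition: NetworkPartition) -> list[SubjectRecord]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            read_timeseries_table(
                manifest_path.parent / row.path,
                partition,
                subject_id=str(row.subject_id),
                group=str(row.group),
                tr_seconds=float(row.tr_seconds),
            )
        )
    return records


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    for key in ("bandpass", "k_grid"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["bandpass"] = list(d["bandpass"])
    if d.get("k_grid") is not None:
        d["k_grid"] = list(d["k_grid"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
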