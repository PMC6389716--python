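"""Reading and writing subject time series and cohort manifests.

File conventions: tab-separated for ``.tsv``, comma-separated for ``.csv``,
decimal point ``.``, UTF-8.  Time-series files are T volumes x M nodes with
an optional header row of 1-based node indices; when the header is present
columns are reordered to partition order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .partition import NetworkPartition

GROUP_ALIASES = {
    "control": "control",
    "nc": "control",
    "hc": "control",
    "patient": "patient",
    "pd": "patient",
}

MANIFEST_COLUMNS = ["subject_id", "group", "path", "age", "sex", "updrs3", "hy"]


class TimeSeriesError(ValueError):
    """Invalid subject time-series matrix."""


class ManifestError(ValueError):
    """Invalid cohort manifest."""


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's preprocessed ROI signal matrix.

    ``data`` has one row per acquired volume (in scan order) and one column
    per node, in partition storage order. ``tr_seconds`` is the sampling
    interval between volumes.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise TimeSeriesError(f"{self.subject_id}: need a T x M matrix with T >= 2")
        if not np.all(np.isfinite(arr)):
            raise TimeSeriesError(f"{self.subject_id}: missing or non-finite values")
        var = arr.var(axis=0)
        dead = np.flatnonzero(var == 0)
        if dead.size:
            raise TimeSeriesError(
                f"{self.subject_id}: zero-variance column(s) at node index "
                f"{(dead + 1).tolist()}"
            )
        if self.tr_seconds <= 0:
            raise TimeSeriesError("tr_seconds must be positive")
        object.__setattr__(self, "data", arr)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_timeseries(
    path: str | Path,
    partition: NetworkPartition,
    tr_seconds: float,
    subject_id: str | None = None,
) -> SubjectTimeSeries:
    """Read one subject's T x M matrix, validating against the partition.

    A first row consisting exactly of the partition's node indices is taken
    as a header and used to reorder columns into partition order; otherwise
    the file is accepted in partition order as-is.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), header=None)
    if raw.shape[1] != partition.n_nodes:
        raise TimeSeriesError(
            f"{path}: {raw.shape[1]} columns but partition has {partition.n_nodes} nodes"
        )
    first = raw.iloc[0].to_numpy()
    arr = raw.to_numpy()
    header_like = False
    try:
        as_int = first.astype(float).astype(int)
        header_like = np.array_equal(np.sort(as_int), partition.node_index) and np.array_equal(
            first.astype(float), as_int.astype(float)
        )
    except (ValueError, TypeError):
        raise TimeSeriesError(f"{path}: non-numeric values") from None
    if header_like:
        # partition storage order is ascending node_index
        col_order = np.argsort(as_int)
        arr = arr[1:].astype(float)[:, col_order]
    else:
        arr = arr.astype(float)
    if np.isnan(arr).any():
        raise TimeSeriesError(f"{path}: missing values")
    return SubjectTimeSeries(
        subject_id=subject_id or path.stem, data=arr, tr_seconds=float(tr_seconds)
    )


def write_timeseries(series: SubjectTimeSeries, path: str | Path, partition: NetworkPartition) -> None:
    """Write a T x M matrix with a header row of node indices."""
    path = Path(path)
    df = pd.DataFrame(series.data, columns=partition.node_index)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.6f")


@dataclass(frozen=True)
class CohortManifest:
    """Subject table: id, group, time-series path, demographics, clinical scores."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ManifestError(f"manifest missing columns: {sorted(missing)}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ManifestError(f"duplicate subject_id: {dup}")
        groups = df["group"].astype(str).str.strip().str.lower().map(GROUP_ALIASES)
        if groups.isna().any():
            bad = df.loc[groups.isna(), "group"].unique().tolist()
            raise ManifestError(f"unknown group label(s): {bad}")
        df = df.assign(group=groups.to_numpy())
        n_missing = int(df.loc[df["group"] == "patient", "updrs3"].isna().sum())
        if n_missing:
            warnings.warn(
                f"{n_missing} patient(s) lack updrs3; excluded from clinical correlation",
                stacklevel=2,
            )
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def group_ids(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "subject_id"].tolist()


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, sep="\t")
    return CohortManifest(table=df)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False, float_format="%.4f")
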