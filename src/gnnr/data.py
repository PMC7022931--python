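"""Longitudinal dataset container and delimited-text I/O.

A longitudinal two-class omics experiment is stored as a cube
``chi = {X_1, ..., X_T}`` of shape ``(d variables, n samples, T time
points)`` with one class label in {-1, +1} per sample.  Variables live in
rows, matching the convention ``X_t in R^(d x n)`` used throughout the
regression modules.  The same samples are tracked across time, so labels
are stored once; :meth:`LongitudinalDataset.labels_at` exposes the
per-time-point view ``y_t`` that the model formulas are written in.

On disk a dataset is one CSV matrix per time point (``X_t1.csv`` ...,
d rows x n columns, first column = variable id, header = sample ids) plus
``labels.csv``, or a single long-format table with columns
``sample_id, time_id, variable_id, value, label``.  All files are UTF-8,
comma-separated, with a header row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalDataset",
    "VariableGroundTruth",
    "load_dataset",
    "write_dataset",
    "load_ground_truth",
    "write_ground_truth",
]


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


def _as_str_list(values: Sequence, n: int, prefix: str) -> list[str]:
    if values is None:
        return [f"{prefix}{i + 1}" for i in range(n)]
    out = [str(v) for v in values]
    if len(out) != n:
        raise DatasetError(f"expected {n} {prefix} ids, got {len(out)}")
    return out


@dataclass
class LongitudinalDataset:
    """A cube of measurements with one binary label per tracked sample.

    Parameters
    ----------
    cube
        Array of shape ``(d, n, T)``: ``cube[:, :, t]`` is the matrix
        ``X_t`` with variables in rows and samples in columns.
    labels
        Integer array of shape ``(n,)`` with entries in {-1, +1} (samples
        are tracked longitudinally), or ``(n, T)`` for per-time labels.
    """

    cube: np.ndarray
    labels: np.ndarray
    variable_ids: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    time_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim != 3:
            raise DatasetError(f"cube must be 3-d (d, n, T), got shape {self.cube.shape}")
        d, n, T = self.cube.shape
        if d < 1 or n < 2 or T < 1:
            raise DatasetError(f"need d >= 1, n >= 2, T >= 1; got ({d}, {n}, {T})")
        if not np.isfinite(self.cube).all():
            raise DatasetError("cube contains missing or non-finite values")
        labels = np.asarray(self.labels)
        if labels.ndim == 1:
            if labels.shape != (n,):
                raise DatasetError(f"labels must have length n={n}, got {labels.shape}")
        elif labels.ndim == 2:
            if labels.shape != (n, T):
                raise DatasetError(f"per-time labels must be (n, T)=({n}, {T}), got {labels.shape}")
        else:
            raise DatasetError("labels must be 1-d (shared) or 2-d (per time point)")
        if not np.isin(labels, (-1, 1)).all():
            raise DatasetError("labels must be -1 or +1")
        self.labels = labels.astype(int)
        for t in range(T):
            y = self.labels_at(t)
            if not ((y == 1).any() and (y == -1).any()):
                raise DatasetError(f"both classes must be present at time point {t}")
        self.variable_ids = _as_str_list(self.variable_ids, d, "v")
        self.sample_ids = _as_str_list(self.sample_ids, n, "s")
        self.time_ids = _as_str_list(self.time_ids, T, "t")

    @property
    def n_variables(self) -> int:
        return self.cube.shape[0]

    @property
    def n_samples(self) -> int:
        return self.cube.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.cube.shape[2]

    def matrix_at(self, t: int) -> np.ndarray:
        """The ``(d, n)`` matrix ``X_t``."""
        return self.cube[:, :, t]

    def labels_at(self, t: int) -> np.ndarray:
        """The label vector ``y_t`` (shared across time unless per-time)."""
        return self.labels if self.labels.ndim == 1 else self.labels[:, t]

    def subset_samples(self, idx: Sequence[int]) -> "LongitudinalDataset":
        """Dataset restricted to the given sample indices (e.g. a CV fold)."""
        idx = np.asarray(idx, dtype=int)
        return LongitudinalDataset(
            cube=self.cube[:, idx, :],
            labels=self.labels[idx],
            variable_ids=list(self.variable_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            time_ids=list(self.time_ids),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LongitudinalDataset):
            return NotImplemented
        return (
            np.array_equal(self.cube, other.cube)
            and np.array_equal(self.labels, other.labels)
            and self.variable_ids == other.variable_ids
            and self.sample_ids == other.sample_ids
            and self.time_ids == other.time_ids
        )


@dataclass
class VariableGroundTruth:
    """Generator-side truth: which group each variable belongs to and at
    which time points each group's class means differ.

    Group ids follow the simulation convention: profile groups carry small
    positive ids and the uninformative background group is the largest id
    (9 under the default design); background variables are discriminative
    at no time point.
    """

    group_ids: np.ndarray  # (d,) integer group id per variable
    discriminative_at: Mapping[int, frozenset[int]]  # group id -> time indices

    def __post_init__(self) -> None:
        self.group_ids = np.asarray(self.group_ids, dtype=int)
        self.discriminative_at = {
            int(g): frozenset(int(t) for t in ts) for g, ts in self.discriminative_at.items()
        }
        missing = set(np.unique(self.group_ids)) - set(self.discriminative_at)
        if missing:
            raise DatasetError(f"groups without discriminative_at entry: {sorted(missing)}")

    @property
    def groups(self) -> list[int]:
        return sorted(self.discriminative_at)

    def members(self, group: int) -> np.ndarray:
        """Indices of the variables in ``group``."""
        return np.flatnonzero(self.group_ids == group)

    def uninformative_mask(self) -> np.ndarray:
        """Boolean mask of variables never discriminative at any time."""
        dead = {g for g, ts in self.discriminative_at.items() if not ts}
        return np.isin(self.group_ids, sorted(dead))


# ---------------------------------------------------------------------------
# I/O


def _load_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df


def load_dataset(paths, label_path=None) -> LongitudinalDataset:
    """Load a dataset from per-time-point CSV matrices or a long table.

    Parameters
    ----------
    paths
        Either a sequence of CSV matrix paths (one per time point, variables
        in rows, samples in columns) or a single path to a long-format table
        with columns ``sample_id, time_id, variable_id, value, label``.
    label_path
        ``labels.csv`` with columns ``sample_id, label``; required with
        per-time matrices, ignored for the long format.
    """
    if isinstance(paths, (str, Path)):
        return _load_long(Path(paths))
    mats = []
    for p in paths:
        df = _load_matrix(Path(p))
        if df.isna().any().any():
            raise DatasetError(f"missing values in {p}")
        mats.append((Path(p), df))
    first_path, first = mats[0]
    for p, df in mats[1:]:
        if list(df.index) != list(first.index) or list(df.columns) != list(first.columns):
            raise DatasetError(
                f"variable/sample ids in {p} do not match {first_path}"
            )
    if label_path is None:
        raise DatasetError("label_path is required with per-time-point matrices")
    lab = pd.read_csv(label_path)
    lab["sample_id"] = lab["sample_id"].map(str)
    lab = lab.set_index("sample_id")["label"]
    missing = [s for s in first.columns if s not in lab.index]
    if missing:
        raise DatasetError(f"labels missing for samples {missing[:5]}")
    labels = lab.loc[list(first.columns)].to_numpy()
    if not np.isin(labels, (-1, 1)).all():
        raise DatasetError("labels must be -1 or +1")
    cube = np.stack([df.to_numpy(dtype=float) for _, df in mats], axis=2)
    time_ids = [Path(p).stem.removeprefix("X_") for p, _ in mats]
    return LongitudinalDataset(
        cube=cube,
        labels=labels.astype(int),
        variable_ids=list(first.index),
        sample_ids=list(first.columns),
        time_ids=time_ids,
    )


def _load_long(path: Path) -> LongitudinalDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"sample_id", "time_id", "variable_id", "value", "label"}
    if not required.issubset(df.columns):
        raise DatasetError(f"long table must have columns {sorted(required)}")
    for c in ("sample_id", "time_id", "variable_id"):
        df[c] = df[c].map(str)
    sample_ids = list(dict.fromkeys(df["sample_id"]))
    time_ids = list(dict.fromkeys(df["time_id"]))
    variable_ids = list(dict.fromkeys(df["variable_id"]))
    wide = df.pivot_table(
        index="variable_id", columns=["sample_id", "time_id"], values="value", sort=False
    )
    cube = np.empty((len(variable_ids), len(sample_ids), len(time_ids)))
    for si, s in enumerate(sample_ids):
        for ti, t in enumerate(time_ids):
            col = wide[(s, t)].reindex(variable_ids)
            cube[:, si, ti] = col.to_numpy()
    if np.isnan(cube).any():
        raise DatasetError(f"missing (sample, time, variable) cells in {path}")
    lab = df.drop_duplicates("sample_id").set_index("sample_id")["label"]
    labels = lab.loc[sample_ids].to_numpy()
    if not np.isin(labels, (-1, 1)).all():
        raise DatasetError("labels must be -1 or +1")
    return LongitudinalDataset(
        cube=cube,
        labels=labels.astype(int),
        variable_ids=variable_ids,
        sample_ids=sample_ids,
        time_ids=time_ids,
    )


def write_dataset(dataset: LongitudinalDataset, out_dir) -> list[Path]:
    """Write one ``X_<time_id>.csv`` per time point plus ``labels.csv``.

    Floats are written with ``repr`` round-trip precision so that
    ``load_dataset`` reproduces the cube exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for t, tid in enumerate(dataset.time_ids):
        df = pd.DataFrame(
            dataset.matrix_at(t), index=dataset.variable_ids, columns=dataset.sample_ids
        )
        df.index.name = "variable_id"
        p = out / f"X_{tid}.csv"
        df.to_csv(p)
        written.append(p)
    if dataset.labels.ndim != 1:
        raise DatasetError("write_dataset supports shared (1-d) labels only")
    lab = pd.DataFrame({"sample_id": dataset.sample_ids, "label": dataset.labels})
    p = out / "labels.csv"
    lab.to_csv(p, index=False)
    written.append(p)
    return written


def dataset_paths(out_dir, time_ids: Sequence[str]):
    """Matrix and label paths that :func:`write_dataset` produced."""
    out = Path(out_dir)
    return [out / f"X_{tid}.csv" for tid in time_ids], out / "labels.csv"


def write_ground_truth(truth: VariableGroundTruth, variable_ids: Sequence[str], out_dir) -> list[Path]:
    """Write ``groups.csv`` (variable_id, group_id) and the per-group
    discriminative time indices as ``discriminative_at.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = pd.DataFrame({"variable_id": list(variable_ids), "group_id": truth.group_ids})
    p1 = out / "groups.csv"
    groups.to_csv(p1, index=False)
    p2 = out / "discriminative_at.json"
    p2.write_text(
        json.dumps({str(g): sorted(ts) for g, ts in truth.discriminative_at.items()}, indent=1)
    )
    return [p1, p2]


def load_ground_truth(out_dir) -> VariableGroundTruth:
    out = Path(out_dir)
    groups = pd.read_csv(out / "groups.csv")
    disc = json.loads((out / "discriminative_at.json").read_text())
    return VariableGroundTruth(
        group_ids=groups["group_id"].to_numpy(),
        discriminative_at={int(g): frozenset(ts) for g, ts in disc.items()},
    )
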