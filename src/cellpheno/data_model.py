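"""Domain types and tabular I/O.

The package consumes long-format per-cell-per-frame tables as exported by
CellProfiler-style image processing pipelines: one row per tracked cell per
movie frame, carrying screen metadata (movie, plate, knockdown role, gene,
siRNA), the trajectory identifier, the frame index, a division-event flag
and a fixed-length vector of numeric morphological features.  No images are
read; the table is the interface.

In memory a cell table is a :class:`pandas.DataFrame` with the canonical
metadata columns of :data:`METADATA_COLUMNS` plus an arbitrary number of
feature columns (every non-metadata column is a feature).  Frames are
0-based integers; physical time is ``frame × 30 min`` (the acquisition
interval of the screens this models) and the conversion happens only at
reporting time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParseError, SchemaError

#: Canonical metadata columns, in canonical order.
METADATA_COLUMNS = (
    "movie_id",
    "plate_id",
    "role",
    "gene",
    "sirna_id",
    "trajectory_id",
    "frame",
    "is_division",
)

ROLE_KNOCKDOWN = "knockdown"
ROLE_CONTROL = "negative_control"
ROLES = (ROLE_KNOCKDOWN, ROLE_CONTROL)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Return the feature columns of a cell table (everything non-metadata)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


@dataclass
class Trajectory:
    """Time-ordered observations of one tracked cell.

    Attributes
    ----------
    trajectory_id, movie_id
        Identifiers of the track and its movie.
    frames
        Strictly increasing integer frame indices.
    X
        ``(len(frames), p)`` feature matrix, row *i* observed at ``frames[i]``.
    division_times
        Frames (a subset of ``frames``) at which this cell divides.  The
        division frame belongs to the mother cell.
    """

    trajectory_id: object
    movie_id: object
    frames: np.ndarray
    X: np.ndarray
    division_times: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.division_times = np.asarray(self.division_times, dtype=int)
        if self.X.shape[0] != self.frames.shape[0]:
            raise IntegrityError(
                f"trajectory {self.trajectory_id!r}: {self.X.shape[0]} feature rows "
                f"for {self.frames.shape[0]} frames"
            )
        if np.any(np.diff(self.frames) <= 0):
            raise IntegrityError(f"trajectory {self.trajectory_id!r}: frames not strictly increasing")
        if self.division_times.size and not np.isin(self.division_times, self.frames).all():
            raise IntegrityError(
                f"trajectory {self.trajectory_id!r}: division_times not a subset of frames"
            )

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def span(self) -> int:
        """Length of the track in frames (last observed minus first)."""
        return int(self.frames[-1] - self.frames[0])


def validate_cell_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and structural invariants of a cell table.

    Raises
    ------
    SchemaError
        If a canonical column is missing.
    IntegrityError
        If ``(movie_id, trajectory_id, frame)`` is not unique, a control row
        carries gene/siRNA annotation, or a role value is unknown.
    ParseError
        If a feature column contains a non-numeric value.
    """
    for col in METADATA_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"missing required column {col!r}")
    dup = table.duplicated(subset=["movie_id", "trajectory_id", "frame"])
    if dup.any():
        row = table.index[dup][0]
        raise IntegrityError(f"duplicate (movie_id, trajectory_id, frame) at row {row}")
    bad_role = ~table["role"].isin(ROLES)
    if bad_role.any():
        raise IntegrityError(f"unknown role value {table.loc[bad_role, 'role'].iloc[0]!r}")
    ctrl = table["role"] == ROLE_CONTROL
    if ctrl.any():
        annotated = table.loc[ctrl, ["gene", "sirna_id"]].notna().any(axis=1)
        if annotated.any():
            raise IntegrityError("negative_control rows must have null gene and sirna_id")
    feats = feature_columns(table)
    for col in feats:
        if not pd.api.types.is_numeric_dtype(table[col]):
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = coerced.isna() & table[col].notna()
            if bad.any():
                raise ParseError(f"non-numeric feature value in column {col!r} at row {table.index[bad][0]}")
            table = table.assign(**{col: coerced})
    return table


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited cell table, optionally remapping column names.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Optional mapping ``{canonical_name: column_name_in_file}`` so native
        exports can be adapted without rewriting the file.
    sep
        Field delimiter, ``","`` by default.
    """
    table = pd.read_csv(path, sep=sep)
    if schema:
        rename = {src: canon for canon, src in schema.items() if src in table.columns}
        missing = [canon for canon, src in schema.items() if src not in table.columns]
        if missing:
            raise SchemaError(f"mapped column(s) not found in file: {missing}")
        table = table.rename(columns=rename)
    table = validate_cell_table(table)
    table["is_division"] = table["is_division"].astype(bool)
    table["frame"] = table["frame"].astype(int)
    return table.sort_values(["movie_id", "trajectory_id", "frame"], kind="stable").reset_index(drop=True)


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table as CSV (inverse of :func:`read_cell_table`)."""
    table.to_csv(path, index=False)


def to_trajectories(table: pd.DataFrame) -> dict[object, list[Trajectory]]:
    """Group a validated cell table into per-movie trajectory lists.

    Rows are sorted by frame within each trajectory; the division flag is
    converted into the trajectory's ``division_times``.
    """
    feats = feature_columns(table)
    out: dict[object, list[Trajectory]] = {}
    for (movie_id, traj_id), grp in table.groupby(["movie_id", "trajectory_id"], sort=True):
        grp = grp.sort_values("frame", kind="stable")
        frames = grp["frame"].to_numpy(dtype=int)
        traj = Trajectory(
            trajectory_id=traj_id,
            movie_id=movie_id,
            frames=frames,
            X=grp[feats].to_numpy(dtype=float),
            division_times=frames[grp["is_division"].to_numpy(dtype=bool)],
        )
        out.setdefault(movie_id, []).append(traj)
    return out


def trajectories_to_table(
    movies: Mapping[object, Sequence[Trajectory]],
    movie_meta: Mapping[object, Mapping[str, object]],
    feature_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Flatten trajectories back into the long cell-table format.

    ``movie_meta`` supplies per-movie ``plate_id``, ``role``, ``gene`` and
    ``sirna_id``; no rows are lost (inverse of :func:`to_trajectories`).
    """
    chunks = []
    for movie_id, trajs in movies.items():
        meta = movie_meta[movie_id]
        for traj in trajs:
            p = traj.X.shape[1]
            names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(p)]
            df = pd.DataFrame(traj.X, columns=names)
            df.insert(0, "movie_id", movie_id)
            df.insert(1, "plate_id", meta.get("plate_id"))
            df.insert(2, "role", meta.get("role"))
            df.insert(3, "gene", meta.get("gene"))
            df.insert(4, "sirna_id", meta.get("sirna_id"))
            df.insert(5, "trajectory_id", traj.trajectory_id)
            df.insert(6, "frame", traj.frames)
            df.insert(7, "is_division", np.isin(traj.frames, traj.division_times))
            chunks.append(df)
    return pd.concat(chunks, ignore_index=True)


def divisions_from_parent_links(
    tracking: pd.DataFrame,
    trajectory_col: str = "trajectory_id",
    parent_col: str = "parent_trajectory_id",
    frame_col: str = "frame",
) -> pd.DataFrame:
    """Derive the per-row division flag from parent/child track links.

    Adapter for trackers that report lineage as parent-object columns instead
    of an event flag.  A trajectory whose ``parent_col`` names another track
    marks a division on the parent's last observed frame (the division frame
    belongs to the mother).  Returns a copy with an ``is_division`` column.
    """
    out = tracking.copy()
    out["is_division"] = False
    last_frame = out.groupby(trajectory_col)[frame_col].max()
    parents = out.loc[out[parent_col].notna(), parent_col].unique()
    for parent in parents:
        if parent in last_frame.index:
            mask = (out[trajectory_col] == parent) & (out[frame_col] == last_frame[parent])
            out.loc[mask, "is_division"] = True
    return out


# ---------------------------------------------------------------------------
# JSON report serialization
#
# Report-like objects (fitted models, abnormal-state reports, fingerprints)
# register themselves under a `kind` tag; write_report/read_report round-trip
# them through JSON exactly (Python's json writes full double precision).

_REGISTRY: dict[str, type] = {}


def serializable(kind: str):
    """Class decorator registering ``to_dict``/``from_dict`` types for report I/O."""

    def wrap(cls):
        cls._report_kind = kind
        _REGISTRY[kind] = cls
        return cls

    return wrap


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(obj, path: str | Path) -> None:
    """Serialize a registered report object to a JSON file."""
    kind = getattr(obj, "_report_kind", None)
    if kind is None or kind not in _REGISTRY:
        raise TypeError(f"{type(obj).__name__} is not a registered report type")
    payload = {"kind": kind, "payload": _jsonable(obj.to_dict())}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_report(path: str | Path):
    """Read back a report written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text())
    kind = payload.get("kind")
    if kind not in _REGISTRY:
        raise TypeError(f"unknown report kind {kind!r}")
    return _REGISTRY[kind].from_dict(payload["payload"])
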