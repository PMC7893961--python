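"""Trajectory file I/O: comma-delimited text with header ``id,time,x,y``."""

from __future__ import annotations

import json
import os

import pandas as pd

from .model import Trajectory

__all__ = ["read_trajectories", "write_trajectories"]

_COLUMNS = ["id", "time", "x", "y"]


def read_trajectories(path: str) -> list:
    """Parse a delimited trajectory file into per-individual trajectories.

    Rows are grouped by ``id`` and sorted by ``time``; duplicate
    ``(id, time)`` pairs and malformed rows raise errors naming the
    offending line.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trajectory file")
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"{path}: expected header 'id,time,x,y', got {list(df.columns)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for col in ("time", "x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: malformed value in column '{col}' at line {line}")
        df[col] = coerced
    dup = df.duplicated(subset=["id", "time"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ValueError(f"{path}: duplicate (id, time) at line {line}")
    out = []
    for ind, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("time")
        out.append(
            Trajectory(
                individual_id=str(ind),
                times=grp["time"].to_numpy(float),
                values=grp[["x", "y"]].to_numpy(float),
            )
        )
    return out


def write_trajectories(path: str, trajectories, metadata: dict = None) -> None:
    """Write trajectories as ``id,time,x,y`` CSV (12-significant-digit floats).

    If ``metadata`` is given, a sidecar ``<path>.meta.json`` records it
    (generator parameters, seeds) so the file can be regenerated exactly.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    with open(path, "w") as fh:
        fh.write("id,time,x,y\n")
        for traj in trajectories:
            for t, (x, y) in zip(traj.times, traj.values):
                fh.write(f"{traj.individual_id},{t:.12g},{x:.12g},{y:.12g}\n")
    if metadata is not None:
        with open(path + ".meta.json", "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")
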