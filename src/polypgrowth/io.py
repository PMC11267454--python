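"""Reading and writing the delimited-text trajectory and event tables.

Both formats are plain CSV (header row, UTF-8, '.' decimal) with fixed,
unit-bearing column names so files are self-describing. Readers validate
schema and value constraints and report the offending column/rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import EVENT_COLUMNS, TRAJECTORY_COLUMNS

__all__ = ["read_trajectories", "write_trajectories", "read_events", "write_events"]


def write_trajectories(traj: pd.DataFrame, path) -> None:
    _check_columns(traj, TRAJECTORY_COLUMNS, "trajectory")
    traj.to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    """Read and validate a longitudinal body-size table.

    Raises ``ValueError`` naming the offending column or row indices for:
    missing columns, non-positive sizes on alive records, and duplicated
    (individual, day) pairs.
    """
    df = pd.read_csv(path)
    _check_columns(df, TRAJECTORY_COLUMNS, "trajectory")
    df["alive"] = df["alive"].astype(bool)
    df["day"] = df["day"].astype(float)
    alive = df[df["alive"]]
    bad = alive.index[~(alive["body_area_mm2"] > 0)].tolist()
    if bad:
        raise ValueError(f"non-positive body_area_mm2 for alive records at rows {bad[:10]}")
    dup = df.duplicated(subset=["individual_id", "day"], keep=False)
    if dup.any():
        raise ValueError(f"duplicated (individual_id, day) pairs at rows "
                         f"{df.index[dup].tolist()[:10]}")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    cols = [c for c in EVENT_COLUMNS if c in events.columns]
    _check_columns(events, [c for c in EVENT_COLUMNS if c != "truth_label"], "event")
    events[cols].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Read and validate a per-event cytometry table (truth_label optional)."""
    df = pd.read_csv(path)
    required = [c for c in EVENT_COLUMNS if c != "truth_label"]
    _check_columns(df, required, "event")
    vals = df[required].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        rows = np.nonzero(~np.isfinite(vals).all(axis=1))[0].tolist()
        raise ValueError(f"non-finite intensities at rows {rows[:10]}")
    if np.any(vals < 0):
        rows = np.nonzero((vals < 0).any(axis=1))[0].tolist()
        raise ValueError(f"negative intensities at rows {rows[:10]}")
    return df


def _check_columns(df: pd.DataFrame, required, kind: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table is missing columns: {missing}")
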