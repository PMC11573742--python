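"""Canonical file formats.

Trajectories are comma-delimited text with columns
``t_s, x, z, heading_deg, v, omega, in_safe_zone, shock_on, stalled``
(flags as 0/1), written at 6 significant digits; sessions are JSON
(metadata plus per-trial summaries).  Readers validate the schema and
report offending line numbers.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
import pandas as pd

TRAJECTORY_COLUMNS = [
    "t_s",
    "x",
    "z",
    "heading_deg",
    "v",
    "omega",
    "in_safe_zone",
    "shock_on",
    "stalled",
]


class TrajectoryFormatError(ValueError):
    """Schema violation in a trajectory file (message carries line numbers)."""


def trajectory_frame(record) -> pd.DataFrame:
    """Build the canonical trajectory table from a TrialRecord (full
    columns) or a synthetic Trajectory (flag columns zero-filled)."""
    n = len(record.t)

    def col(name, default=0.0):
        v = getattr(record, name, None)
        return np.zeros(n) if v is None else np.asarray(v)

    return pd.DataFrame(
        {
            "t_s": np.asarray(record.t, float),
            "x": np.asarray(record.x, float),
            "z": np.asarray(record.z, float),
            "heading_deg": np.asarray(record.heading_deg, float),
            "v": col("v"),
            "omega": col("omega_deg_s"),
            "in_safe_zone": col("in_safe_zone").astype(int),
            "shock_on": col("shock_on").astype(int),
            "stalled": col("stalled").astype(int),
        }
    )


def write_trajectory(record_or_frame, path) -> None:
    """Write a trajectory as delimited text at 6 significant digits."""
    df = (
        record_or_frame.copy()
        if isinstance(record_or_frame, pd.DataFrame)
        else trajectory_frame(record_or_frame)
    )
    for c in df.columns:
        if df[c].dtype.kind == "f":
            df[c] = df[c] + 0.0  # normalize -0.0 for byte-stable output
    df.to_csv(path, index=False, float_format="%.6g")


def read_trajectory(path, arena_radius: Optional[float] = None) -> pd.DataFrame:
    """Read and validate a trajectory file.

    Checks: required columns, strictly increasing time, and (when
    ``arena_radius`` is given) that every position lies inside the arena.
    Violations raise TrajectoryFormatError naming the first offending data
    line (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {missing}")
    t = df["t_s"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise TrajectoryFormatError(
            f"{path}: time not strictly increasing at line {int(bad[0]) + 3}"
        )
    if arena_radius is not None:
        r2 = df["x"].to_numpy(float) ** 2 + df["z"].to_numpy(float) ** 2
        out = np.flatnonzero(r2 > arena_radius**2 * (1 + 1e-9))
        if out.size:
            raise TrajectoryFormatError(
                f"{path}: position outside arena (radius {arena_radius}) at line {int(out[0]) + 2}"
            )
    return df


def write_session(session, path) -> None:
    """Serialize a SessionRecord's metadata and trial summaries as JSON."""
    with open(path, "w") as fh:
        json.dump(session.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_session(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def session_bytes(session) -> bytes:
    """Deterministic byte serialization (the determinism contract: identical
    config + seed must reproduce these bytes exactly)."""
    return (json.dumps(session.to_dict(), indent=1, sort_keys=True) + "\n").encode()
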