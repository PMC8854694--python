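"""Mesoderm-explant cell migration metrics.

Three per-cell summaries of a manually tracked trajectory:

* movement — total path length in um,
* velocity — movement divided by total elapsed time (um/min),
* directionality — total path length divided by the straight-line distance
  between start and end positions.

Directionality as defined here is >= 1 (1 = perfectly straight). Note this
is the reciprocal of the "directionality ratio" convention common elsewhere
(straight / total, <= 1); pass ``inverse=True`` for that convention. Both
are reported rather than silently re-defined because the source protocol
states the total/straight form verbatim.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["cell_id", "t_min", "x_um", "y_um"]


def _validate(track: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("t_min", "x_um", "y_um") if c not in track.columns]
    if missing:
        raise ValueError(f"track is missing column(s) {missing}")
    if len(track) < 2:
        raise ValueError("a track needs at least 2 samples")
    t = track["t_min"].to_numpy(float)
    if not np.all(np.diff(t) > 0):
        track = track.sort_values("t_min")
        t = track["t_min"].to_numpy(float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("track times must be strictly increasing")
    return track


def movement(track: pd.DataFrame) -> float:
    """Total distance travelled (um): the sum of segment lengths."""
    track = _validate(track)
    xy = track[["x_um", "y_um"]].to_numpy(float)
    return float(np.hypot(*np.diff(xy, axis=0).T).sum())


def velocity(track: pd.DataFrame) -> float:
    """Average speed (um/min): total path length over total elapsed time."""
    track = _validate(track)
    duration = float(track["t_min"].iloc[-1] - track["t_min"].iloc[0])
    if duration <= 0:
        raise ValueError("track duration must be positive")
    return movement(track) / duration


def directionality(track: pd.DataFrame, inverse: bool = False) -> float:
    """Path-length / straight-line-distance ratio (>= 1).

    ``inverse=True`` returns straight/total (in (0, 1]) instead. Undefined
    when start and end coincide.
    """
    track = _validate(track)
    xy = track[["x_um", "y_um"]].to_numpy(float)
    straight = float(np.hypot(*(xy[-1] - xy[0])))
    if straight == 0:
        raise ValueError("directionality undefined: start equals end position")
    total = movement(track)
    return straight / total if inverse else total / straight


def migration_metrics(tracks: pd.DataFrame, inverse: bool = False) -> pd.DataFrame:
    """Per-cell movement, velocity and directionality for a tidy track table.

    Cells whose directionality is undefined (start == end) get NaN there and
    are listed in the ``note`` column rather than dropped.
    """
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table is missing column(s) {missing}")
    rows = []
    for cell, grp in tracks.groupby("cell_id", sort=True):
        rec = {"cell_id": cell, "movement_um": movement(grp),
               "velocity_um_min": velocity(grp), "note": ""}
        try:
            rec["directionality"] = directionality(grp, inverse=inverse)
        except ValueError as exc:
            rec["directionality"] = np.nan
            rec["note"] = str(exc)
        rows.append(rec)
    return pd.DataFrame(rows)
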