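"""Readers and writers for the package's file formats.

Formats are deliberately plain: CSV for track tables and tidy statistics,
multi-page TIFF (pages = time bins) plus a JSON sidecar for decay stacks,
single-page TIFF for lifetime maps, and JSON for ROIs, configs, ground truth
and run reports. Coordinates in track CSVs are micrometres; image inputs in
pixels require an explicit pixel size when converted. All writes are atomic
(write-then-rename), so interrupted runs never leave truncated files.

Lifetime TIFFs follow the vendor-export dialect of storing lifetimes as
integer grey levels at 0.01 ns per level; floating-point TIFFs are taken as
nanoseconds directly.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from epiquant._util import atomic_open, atomic_write_bytes, write_json
from epiquant.flim import FlimStack, LifetimeImage, RoiSet
from epiquant.kinematics import TRACK_COLUMNS

GREY_LEVEL_NS = 0.01  # vendor lifetime-TIFF export scale: ns per grey level


def read_tracks(path, mapping: Optional[dict] = None,
                pixel_size_um: Optional[float] = None) -> pd.DataFrame:
    """Read and validate a track table CSV.

    ``mapping`` renames input columns to the package schema (e.g. a
    TrackMate-style export mapped as ``{"TRACK_ID": "track_id", ...}``).
    If the mapping declares positions in pixels (keys ``x_px``/``y_px`` as
    mapped names), ``pixel_size_um`` is required and coordinates are
    converted. Validates required columns, duplicate (track, frame) rows
    and per-track frame monotonicity.
    """
    df = pd.read_csv(path)
    if mapping:
        df = df.rename(columns=mapping)
    if "x_px" in df.columns or "y_px" in df.columns:
        if pixel_size_um is None:
            raise ValueError("pixel coordinates given; pixel_size_um is required")
        df["x_um"] = df.pop("x_px") * pixel_size_um
        df["y_um"] = df.pop("y_px") * pixel_size_um
        for c in ("centre_x_px", "centre_y_px"):
            if c in df.columns:
                df[c.replace("_px", "_um")] = df.pop(c) * pixel_size_um
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV is missing column(s) {missing}")
    dup = df.duplicated(subset=["embryo_id", "track_id", "frame"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (track, frame) row: track {row['track_id']!r} "
            f"frame {row['frame']} in embryo {row['embryo_id']!r}")
    for (embryo, track), grp in df.groupby(["embryo_id", "track_id"]):
        frames = grp.sort_index()["frame"].to_numpy()
        if not np.all(np.diff(np.sort(frames)) == 1):
            raise ValueError(
                f"frames of track {track!r} in embryo {embryo!r} are not "
                "contiguous")
        if not np.all(np.diff(frames) > 0):
            raise ValueError(
                f"frames of track {track!r} in embryo {embryo!r} are not "
                "monotonically increasing")
    return df


def write_tracks(table: pd.DataFrame, path) -> None:
    with atomic_open(path, "w") as fh:
        table.to_csv(fh, index=False)


def write_csv(df: pd.DataFrame, path) -> None:
    with atomic_open(path, "w") as fh:
        df.to_csv(fh, index=False)


# --------------------------------------------------------------------------
# FLIM stacks and lifetime images
# --------------------------------------------------------------------------

def write_flim_stack(stack: FlimStack, tiff_path, meta_path=None) -> None:
    """Write a decay stack as a multi-page TIFF plus a JSON sidecar."""
    buf = _io.BytesIO()
    tifffile.imwrite(buf, np.asarray(stack.decay), photometric="minisblack")
    atomic_write_bytes(tiff_path, buf.getvalue())
    if meta_path is None:
        meta_path = Path(tiff_path).with_suffix(".json")
    write_json(meta_path, {
        "rep_rate_hz": stack.rep_rate,
        "n_bins": stack.n_bins,
        "pixel_size_nm": stack.pixel_size_nm,
    })


def read_flim_stack(tiff_path, meta_path=None) -> FlimStack:
    if meta_path is None:
        meta_path = Path(tiff_path).with_suffix(".json")
    with open(meta_path) as fh:
        meta = json.load(fh)
    decay = tifffile.imread(tiff_path)
    if decay.ndim == 2:
        decay = decay[None]
    if decay.shape[0] != meta["n_bins"]:
        raise ValueError(
            f"TIFF has {decay.shape[0]} pages but sidecar declares "
            f"{meta['n_bins']} time bins")
    return FlimStack(decay=decay, rep_rate=meta["rep_rate_hz"],
                     pixel_size_nm=meta.get("pixel_size_nm", 135.0))


def read_lifetime_tiff(path, grey_level_scale: float = GREY_LEVEL_NS) -> LifetimeImage:
    """Read a lifetime map TIFF.

    Integer TIFFs are interpreted as grey levels at ``grey_level_scale``
    ns per level (vendor export dialect); float TIFFs are nanoseconds.
    """
    img = tifffile.imread(path)
    if np.issubdtype(img.dtype, np.integer):
        tau = img.astype(float) * grey_level_scale
    else:
        tau = img.astype(float)
    return LifetimeImage(tau=tau)


def write_lifetime_tiff(lt: LifetimeImage, path,
                        as_grey_levels: bool = False,
                        grey_level_scale: float = GREY_LEVEL_NS) -> None:
    buf = _io.BytesIO()
    if as_grey_levels:
        levels = np.round(np.nan_to_num(lt.tau, nan=0.0) / grey_level_scale)
        tifffile.imwrite(buf, levels.astype(np.uint16))
    else:
        tifffile.imwrite(buf, lt.tau.astype(np.float32))
    atomic_write_bytes(path, buf.getvalue())


def read_rois(path) -> RoiSet:
    """Read an ROI set from JSON: {"rois": {name: [[r, c], ...]}, "lifetime_window": [lo, hi]}."""
    with open(path) as fh:
        obj = json.load(fh)
    rois = {name: np.asarray(pts, float) for name, pts in obj["rois"].items()}
    window = tuple(obj.get("lifetime_window", (2.8, 7.0)))
    return RoiSet(rois=rois, lifetime_window=window)


def write_rois(rois: RoiSet, path) -> None:
    write_json(path, {
        "rois": {k: np.asarray(v).tolist() for k, v in rois.rois.items()},
        "lifetime_window": list(rois.lifetime_window),
    })


def write_run_report(path, stage: str, seed=None, parameters=None,
                     exclusions=None, extra=None) -> None:
    """JSON run report: version, stage, seed, parameter echo, exclusion log.

    Every run is reproducible from its report (parameters + seed).
    """
    from epiquant import __version__

    report = {
        "package": "epiquant",
        "version": __version__,
        "stage": stage,
        "seed": seed,
        "parameters": parameters or {},
        "exclusions": exclusions or [],
    }
    if extra:
        report.update(extra)
    write_json(path, report)
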