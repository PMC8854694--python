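"""Small shared helpers: atomic writes, validation, polygon masks."""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
from skimage.draw import polygon2mask


@contextmanager
def atomic_open(path, mode="w"):
    """Open a temporary file and rename it onto *path* only on success.

    Guarantees that a crashed run never leaves a half-written output file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def atomic_write_bytes(path, data: bytes) -> None:
    with atomic_open(path, "wb") as fh:
        fh.write(data)


def write_json(path, obj) -> None:
    with atomic_open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def check_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")


def polygon_mask(shape, polygon) -> np.ndarray:
    """Boolean mask of a polygon given as (row, col) vertices.

    Follows the image convention used throughout the package: 0-based pixel
    indexing, origin at the top-left, first axis = row (y, increasing
    downward), second axis = column (x).
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an (n >= 3, 2) array of (row, col) vertices")
    return polygon2mask(shape, poly)
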