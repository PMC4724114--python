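"""Multi-page TIFF stack readers/writers and JSON sidecars.

Counts are stored as 32-bit unsigned integers, everything else as 32-bit
floats; writing then reading a stack is value-exact for integer counts and
bit-exact for float32 data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile


def write_stack(path, data, dtype=np.float32) -> None:
    """Write an array as a multi-page TIFF (2-D input becomes one page)."""
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("stack must be 2-D or 3-D")
    tifffile.imwrite(str(path), arr.astype(dtype), photometric="minisblack")


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as an array of shape (pages, rows, cols)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_sidecar(path, meta: dict) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
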