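"""TIFF / CSV input-output helpers.

Images travel as multi-page TIFF (channel 1 then channel 2 per field),
float32 for intensity data and uint16 for label masks; tables are plain CSV
with the stable column names defined in :mod:`f2f.detect`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .errors import InputError

__all__ = ["write_stack", "read_stack", "write_mask", "read_mask",
           "read_image_dir"]


def write_stack(path: str | Path, image: np.ndarray) -> None:
    """Write a (C, H, W) two-channel frame as a multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InputError(f"{path}: expected a 2- or 3-D TIFF, got {arr.shape}")
    return arr.astype(np.float32)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(mask, dtype=np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.uint16)


def read_image_dir(directory: str | Path, pattern: str = "*.tif*",
                   ) -> list[np.ndarray]:
    """Read every TIFF stack in a directory, sorted by filename."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise InputError(f"no files matching {pattern!r} in {directory}")
    return [read_stack(p) for p in paths]
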