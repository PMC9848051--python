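"""TIFF volume I/O helpers.

Volumes travel as multi-page TIFFs, one page per z-slice, (z, y, x) in
memory. Raw 8/16-bit images are normalized to [0, 1] on read; float maps
(probabilities, fused volumes) round-trip as float32.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .enhancement import normalize_intensities

__all__ = ["read_volume", "write_volume", "write_mask"]


def read_volume(path: str | Path, normalize: bool = True) -> np.ndarray:
    """Read a multi-page TIFF; integer data is normalized to [0, 1]."""
    vol = tifffile.imread(path)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {vol.shape}")
    if normalize and np.issubdtype(vol.dtype, np.integer):
        return normalize_intensities(vol)
    return vol.astype(np.float32)


def write_volume(path: str | Path, vol: np.ndarray,
                 bit_depth: int | None = None) -> None:
    """Write a volume; float32 by default, or scaled integer with bit_depth."""
    vol = np.asarray(vol)
    if bit_depth is None:
        tifffile.imwrite(path, vol.astype(np.float32))
        return
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    maxval = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    tifffile.imwrite(path, np.rint(np.clip(vol, 0, 1) * maxval).astype(dtype))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as uint8 0/255 (0/1 in memory)."""
    tifffile.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)
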