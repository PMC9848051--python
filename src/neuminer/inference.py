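"""Whole-volume inference by sliding-window tiling.

Volumes larger than one network input are processed in overlapping tiles
whose softmax foreground probabilities are averaged in the overlaps; a
volume no larger than the tile is a single forward pass. Volumes whose
dimensions are not multiples of the network's stride budget are zero-padded
and cropped back.
"""

from __future__ import annotations

import numpy as np

from .nn import UNet3D, softmax

__all__ = ["predict_volume"]


def _tile_starts(extent: int, tile: int, stride: int) -> list[int]:
    if extent <= tile:
        return [0]
    starts = list(range(0, extent - tile, stride))
    starts.append(extent - tile)
    return starts


def predict_volume(network: UNet3D, vol: np.ndarray,
                   tile_xyz=(160, 160, 128), overlap: float = 0.5) -> np.ndarray:
    """Foreground probability map for a (z, y, x) volume, same shape, [0, 1].

    ``tile_xyz`` is the window size in (x, y, z); ``overlap`` is the
    fractional overlap between neighboring windows.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    vol = np.asarray(vol, dtype=np.float32)
    m = 2 ** (network.levels - 1)
    tile = tuple(min(int(t), int(np.ceil(s / m) * m))
                 for t, s in zip(reversed(tile_xyz), vol.shape))
    if any(t % m for t in tile):
        raise ValueError(f"tile {tile_xyz} must be a multiple of {m}")
    pad = [(0, max(t - s, 0)) for t, s in zip(tile, vol.shape)]
    padded = np.pad(vol, pad)
    acc = np.zeros(padded.shape, dtype=np.float64)
    cnt = np.zeros(padded.shape, dtype=np.float64)
    strides = [max(1, int(round(t * (1 - overlap)))) for t in tile]
    for z0 in _tile_starts(padded.shape[0], tile[0], strides[0]):
        for y0 in _tile_starts(padded.shape[1], tile[1], strides[1]):
            for x0 in _tile_starts(padded.shape[2], tile[2], strides[2]):
                sl = (slice(z0, z0 + tile[0]), slice(y0, y0 + tile[1]),
                      slice(x0, x0 + tile[2]))
                logits, _ = network.forward(padded[sl][None, None])
                prob = softmax(logits, axis=1)[0, 1]
                acc[sl] += prob
                cnt[sl] += 1.0
    out = acc / cnt
    out = out[: vol.shape[0], : vol.shape[1], : vol.shape[2]]
    return np.clip(out, 0.0, 1.0)
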