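"""Rasterization of SWC gold standards into voxel label volumes.

Training labels are generated from manual reconstructions by resampling the
tree to connective points, stamping each point with a uniform fiber width of
3 x 3 x 1 voxels (x, y, z) -- axial resolution of whole-brain light
microscopy is coarser, so no dilation in z -- and overlaying the soma with a
fixed 18 x 18 x 6 cuboid. The same cuboid is optionally painted into the
input image, since manual annotations carry no soma outline and a uniform
bright patch removes that ambiguity.

All label volumes are uint8 arrays indexed (z, y, x) with values in {0, 1};
sizes in this module's signatures are quoted (x, y, z).
"""

from __future__ import annotations

import numpy as np

from .swc import SwcTree, resample_tree

__all__ = [
    "rasterize_tree",
    "soma_mask",
    "make_label_volume",
    "paint_soma",
]

FIBER_WIDTH_XYZ = (3, 3, 1)
SOMA_SHAPE_XYZ = (18, 18, 6)


def _check_shape(shape) -> tuple[int, int, int]:
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"volume shape must be 3 positive ints (z,y,x), got {shape}")
    return shape


def rasterize_tree(
    tree: SwcTree,
    shape,
    fiber_width_xyz=FIBER_WIDTH_XYZ,
    step: float = 1.0,
    include_soma_nodes: bool = True,
) -> np.ndarray:
    """Rasterize a tree into a binary (z, y, x) volume.

    Every resampled point is rounded to its nearest voxel and dilated with a
    ``fiber_width_xyz`` structuring element (odd sizes; centered). Points and
    structuring-element voxels falling outside the volume are dropped.
    ``include_soma_nodes=False`` skips points sampled on the root, for
    callers that handle the soma via :func:`soma_mask`.
    """
    shape = _check_shape(shape)
    wx, wy, wz = (int(w) for w in fiber_width_xyz)
    if any(w < 1 or w % 2 == 0 for w in (wx, wy, wz)):
        raise ValueError("fiber width must be odd and >= 1 in every axis")
    vol = np.zeros(shape, dtype=np.uint8)
    if tree.is_empty:
        return vol
    pts, src = resample_tree(tree, step=step, return_nodes=True)
    if not include_soma_nodes:
        keep = src != tree.root.id
        pts = pts[keep]
    if len(pts) == 0:
        return vol
    vox = np.rint(pts).astype(int)  # (N, 3) in (x, y, z)
    vox = np.unique(vox, axis=0)
    nz, ny, nx = shape
    hx, hy, hz = wx // 2, wy // 2, wz // 2
    for x, y, z in vox:
        vol[
            max(z - hz, 0) : min(z + hz + 1, nz),
            max(y - hy, 0) : min(y + hy + 1, ny),
            max(x - hx, 0) : min(x + hx + 1, nx),
        ] = 1
    return vol


def _cuboid_slices(center_xyz, size_xyz, shape_zyx):
    """Floor-centered half-open cuboid [c - s/2, c + s/2), clipped to bounds.

    Even sizes cannot be symmetric about a voxel; this anchoring keeps
    exactly ``s`` voxels per axis when unclipped and is deterministic.
    """
    slices = []
    for c, s, n in zip(reversed(center_xyz), reversed(size_xyz), shape_zyx):
        lo = int(np.floor(c - s / 2))
        slices.append(slice(max(lo, 0), min(lo + int(s), n)))
    return tuple(slices)  # (z, y, x)


def soma_mask(
    tree: SwcTree,
    shape,
    soma_shape_xyz=SOMA_SHAPE_XYZ,
    style: str = "cuboid",
) -> np.ndarray:
    """Binary mask of the soma region centered at the tree root.

    ``style='cuboid'`` (default) paints an 18 x 18 x 6 cuboid (x, y, z);
    ``style='ellipsoid'`` paints the inscribed ellipsoid instead, which
    performs similarly in practice. The mask is clipped at volume bounds.
    """
    shape = _check_shape(shape)
    root = tree.root
    nz, ny, nx = shape
    rz, ry, rx = int(round(root.z)), int(round(root.y)), int(round(root.x))
    if not (0 <= rz < nz and 0 <= ry < ny and 0 <= rx < nx):
        raise ValueError(f"root ({root.x}, {root.y}, {root.z}) outside volume")
    mask = np.zeros(shape, dtype=np.uint8)
    if style == "cuboid":
        mask[_cuboid_slices((root.x, root.y, root.z), soma_shape_xyz, shape)] = 1
    elif style == "ellipsoid":
        sx, sy, sz = soma_shape_xyz
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        d2 = (
            ((xx - root.x) / (sx / 2)) ** 2
            + ((yy - root.y) / (sy / 2)) ** 2
            + ((zz - root.z) / (sz / 2)) ** 2
        )
        mask[d2 <= 1.0] = 1
    else:
        raise ValueError(f"unknown soma style {style!r}")
    return mask


def make_label_volume(
    tree: SwcTree,
    shape,
    fiber_width_xyz=FIBER_WIDTH_XYZ,
    soma_shape_xyz=SOMA_SHAPE_XYZ,
    soma_style: str = "cuboid",
    step: float = 1.0,
) -> np.ndarray:
    """Full label volume: rasterized fibers unioned with the soma mask."""
    vol = rasterize_tree(tree, shape, fiber_width_xyz=fiber_width_xyz, step=step)
    if not tree.is_empty:
        vol |= soma_mask(tree, shape, soma_shape_xyz=soma_shape_xyz, style=soma_style)
    return vol


def paint_soma(
    image: np.ndarray,
    tree: SwcTree,
    soma_shape_xyz=SOMA_SHAPE_XYZ,
    intensity: float | None = None,
) -> np.ndarray:
    """Overlay the soma cuboid into an intensity image (returns a copy).

    The painted value defaults to the image maximum, mirroring how the label
    cuboid marks a uniformly bright soma region in training inputs.
    """
    out = np.array(image, copy=True)
    value = float(out.max()) if intensity is None else float(intensity)
    root = tree.root
    out[_cuboid_slices((root.x, root.y, root.z), soma_shape_xyz, out.shape)] = value
    return out
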