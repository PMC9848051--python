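"""Fusing segmentation confidence with the image, and tracing the result.

The segmentation probability map is blended with the (normalized) original
image by a convex combination ``fused = alpha * image + (1 - alpha) * prob``
with ``alpha = 0.8``: the image keeps its fine intensity structure while
low-confidence background is damped and weak-but-detected fibers are
lifted. The fused volume is what a tracer consumes.

The built-in tracer is a deliberately simple skeleton extractor (threshold
-> soma-connected component -> 3D skeletonization -> shortest-path spanning
tree), sufficient for end-to-end evaluation on phantoms; real pipelines can
export the fused volume and run a production tracer on it out of band.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import measure, morphology

from .swc import SwcNode, SwcTree, SOMA_TYPE, AXON_TYPE

__all__ = ["DEFAULT_ALPHA", "DisconnectedSomaError", "fuse_volumes",
           "extract_reconstruction"]

DEFAULT_ALPHA = 0.8


class DisconnectedSomaError(RuntimeError):
    """The soma voxel is below threshold / detached from any foreground."""


def fuse_volumes(image: np.ndarray, prob: np.ndarray,
                 alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Convex combination alpha*image + (1-alpha)*prob, elementwise.

    ``alpha=1`` returns the image exactly, ``alpha=0`` the probability map.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    image = np.asarray(image, dtype=np.float64)
    prob = np.asarray(prob, dtype=np.float64)
    if image.shape != prob.shape:
        raise ValueError("image and probability map shapes differ")
    for name, vol in (("image", image), ("prob", prob)):
        if vol.size and (vol.min() < 0 or vol.max() > 1):
            raise ValueError(f"{name} must be in [0, 1]")
    if alpha == 1.0:
        return image.copy()
    if alpha == 0.0:
        return prob.copy()
    return alpha * image + (1.0 - alpha) * prob


def _skeleton_graph(skel: np.ndarray):
    """Sparse weighted 26-connectivity graph over skeleton voxels."""
    coords = np.argwhere(skel)  # (N, 3) in (z, y, x)
    index = -np.ones(skel.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(len(coords))
    rows, cols, weights = [], [], []
    nz, ny, nx = skel.shape
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) <= (0, 0, 0):
                    continue  # each unordered pair once
                nb = coords + (dz, dy, dx)
                ok = ((nb >= 0).all(1) & (nb[:, 0] < nz)
                      & (nb[:, 1] < ny) & (nb[:, 2] < nx))
                src = index[tuple(coords[ok].T)]
                dst = index[tuple(nb[ok].T)]
                valid = dst >= 0
                rows.append(src[valid])
                cols.append(dst[valid])
                weights.append(np.full(valid.sum(),
                                       np.sqrt(dz**2 + dy**2 + dx**2)))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    n = len(coords)
    g = coo_matrix((weights, (rows, cols)), shape=(n, n))
    return coords, (g + g.T).tocsr()


def extract_reconstruction(fused: np.ndarray, threshold: float,
                           soma_xyz, min_component: int = 1) -> SwcTree:
    """Trace a fused volume into a single-root SWC tree.

    Pipeline: binarize at ``threshold``; keep the connected component
    containing the soma; skeletonize it; build the 26-connected voxel graph
    of the skeleton; take the shortest-path spanning tree rooted at the
    skeleton voxel nearest the soma. Raises
    :class:`DisconnectedSomaError` when the soma voxel itself is below
    threshold -- the classic failure mode of a prediction that detaches
    near the soma.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    fused = np.asarray(fused)
    nz, ny, nx = fused.shape
    sx, sy, sz = (int(round(v)) for v in soma_xyz)
    if not (0 <= sz < nz and 0 <= sy < ny and 0 <= sx < nx):
        raise ValueError("soma position outside the volume")
    binary = fused >= threshold
    if not binary[sz, sy, sx]:
        raise DisconnectedSomaError(
            f"soma voxel ({sx}, {sy}, {sz}) is below threshold {threshold}")
    comp = measure.label(binary, connectivity=3)
    binary = comp == comp[sz, sy, sx]
    skel = morphology.skeletonize(binary)
    if not skel.any():
        # a tiny blob can skeletonize to nothing; keep the soma voxel
        skel = np.zeros_like(binary)
        skel[sz, sy, sx] = True
    coords, graph = _skeleton_graph(skel)
    # root at the skeleton voxel nearest the soma
    d2 = ((coords - (sz, sy, sx)) ** 2).sum(axis=1)
    root_idx = int(d2.argmin())
    dist, pred = dijkstra(graph, directed=False, indices=root_idx,
                          return_predecessors=True)
    reachable = np.isfinite(dist)
    order = np.argsort(dist[reachable])
    idxs = np.flatnonzero(reachable)[order]
    swc_id = {int(i): n + 1 for n, i in enumerate(idxs)}
    nodes = []
    for i in idxs:
        z, y, x = coords[i]
        parent = int(pred[i])
        if parent < 0:
            pid, code = -1, SOMA_TYPE
        else:
            pid, code = swc_id[parent], AXON_TYPE
        nodes.append(SwcNode(swc_id[int(i)], code, float(x), float(y),
                             float(z), 1.0, pid))
    return SwcTree(nodes)
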