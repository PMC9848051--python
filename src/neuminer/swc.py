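"""SWC neuron morphology trees: parsing, writing, traversal and resampling.

The SWC format is the field's standard plain-text exchange format for neuron
reconstructions: one node per line with seven whitespace-separated columns
``id type x y z radius parent_id`` where ``parent_id == -1`` marks the root.
Coordinates here are in voxel units of the working image, 0-based, with voxel
centers at integer coordinates. Arrays elsewhere in the package are indexed
``(z, y, x)`` while SWC stores ``(x, y, z)``; conversions happen at the array
boundary, never silently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "SwcNode",
    "SwcTree",
    "SwcParseError",
    "read_swc",
    "write_swc",
    "resample_tree",
]

SOMA_TYPE = 1
AXON_TYPE = 2
DENDRITE_TYPE = 3


class SwcParseError(ValueError):
    """Raised for malformed SWC content; the message names the offending line."""


@dataclass(frozen=True)
class SwcNode:
    """A single SWC node. ``type_code`` 1 marks the soma."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class SwcTree:
    """A rooted tree of :class:`SwcNode` with exactly one root.

    Node ids are unique; every ``parent_id`` references an existing node or
    is ``-1``. Construction validates these invariants and rejects cycles and
    multi-root forests.
    """

    def __init__(self, nodes: Iterable[SwcNode]):
        self._nodes: dict[int, SwcNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise SwcParseError(f"duplicate node id {node.id}")
            self._nodes[node.id] = node
        roots = [n for n in self._nodes.values() if n.parent_id == -1]
        if len(self._nodes) and len(roots) != 1:
            raise SwcParseError(
                f"tree must have exactly one root, found {len(roots)}"
            )
        for node in self._nodes.values():
            if node.parent_id != -1 and node.parent_id not in self._nodes:
                raise SwcParseError(
                    f"node {node.id} references missing parent {node.parent_id}"
                )
        self._children: dict[int, list[int]] = {i: [] for i in self._nodes}
        for node in self._nodes.values():
            if node.parent_id != -1:
                self._children[node.parent_id].append(node.id)
        self._root_id = roots[0].id if roots else None
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        if self._root_id is None:
            return
        seen: set[int] = set()
        stack = [self._root_id]
        while stack:
            nid = stack.pop()
            seen.add(nid)
            stack.extend(self._children[nid])
        if len(seen) != len(self._nodes):
            raise SwcParseError("parent chain contains a cycle or detached subtree")

    # -- basic container protocol ------------------------------------------
    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[SwcNode]:
        return iter(self._nodes.values())

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SwcTree):
            return NotImplemented
        return list(self) == list(other)

    def node(self, node_id: int) -> SwcNode:
        return self._nodes[node_id]

    def children(self, node_id: int) -> list[SwcNode]:
        return [self._nodes[c] for c in self._children[node_id]]

    @property
    def root(self) -> SwcNode:
        if self._root_id is None:
            raise ValueError("empty tree has no root")
        return self._nodes[self._root_id]

    @property
    def is_empty(self) -> bool:
        return not self._nodes

    # -- geometry -----------------------------------------------------------
    def coordinates(self) -> np.ndarray:
        """All node coordinates as an (N, 3) array in (x, y, z) order."""
        if not self._nodes:
            return np.zeros((0, 3))
        return np.array([[n.x, n.y, n.z] for n in self._nodes.values()])

    def segments(self) -> Iterator[tuple[SwcNode, SwcNode]]:
        """Yield (parent, child) node pairs for every edge."""
        for node in self._nodes.values():
            if node.parent_id != -1:
                yield self._nodes[node.parent_id], node

    def total_length(self) -> float:
        """Total cable length: sum of Euclidean parent-child distances."""
        return float(
            sum(np.linalg.norm(p.xyz - c.xyz) for p, c in self.segments())
        )

    def subtree_ids(self, node_id: int) -> set[int]:
        """Ids of ``node_id`` and all its descendants."""
        out: set[int] = set()
        stack = [node_id]
        while stack:
            nid = stack.pop()
            out.add(nid)
            stack.extend(self._children[nid])
        return out

    def without(self, node_ids: set[int]) -> "SwcTree":
        """A new tree with the given nodes removed (must not include the root)."""
        if self._root_id in node_ids:
            raise ValueError("cannot remove the root")
        kept = [n for n in self._nodes.values() if n.id not in node_ids]
        for n in kept:
            if n.parent_id != -1 and n.parent_id in node_ids:
                raise ValueError("removal must take whole subtrees")
        return SwcTree(kept)

    def translated(self, dx: float, dy: float, dz: float) -> "SwcTree":
        return SwcTree(
            replace(n, x=n.x + dx, y=n.y + dy, z=n.z + dz) for n in self
        )


def read_swc(path: str | Path) -> SwcTree:
    """Parse a 7-column SWC file. Lines starting with '#' are comments."""
    nodes: list[SwcNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nodes.append(
                    SwcNode(
                        id=int(parts[0]),
                        type_code=int(parts[1]),
                        x=float(parts[2]),
                        y=float(parts[3]),
                        z=float(parts[4]),
                        radius=float(parts[5]),
                        parent_id=int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SwcParseError(f"{path}:{lineno}: {exc}") from exc
    try:
        return SwcTree(nodes)
    except SwcParseError as exc:
        raise SwcParseError(f"{path}: {exc}") from exc


def write_swc(tree: SwcTree, path: str | Path) -> None:
    """Write a tree as standard 7-column SWC with 4-decimal coordinates."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in tree:
            fh.write(
                f"{n.id} {n.type_code} {n.x:.4f} {n.y:.4f} {n.z:.4f} "
                f"{n.radius:.4f} {n.parent_id}\n"
            )


def resample_tree(
    tree: SwcTree, step: float = 1.0, return_nodes: bool = False
):
    """Resample a tree to connective points along every parent-child segment.

    Each segment is linearly interpolated at spacing <= ``step`` with both
    endpoints included, so consecutive points on a segment are never more
    than ``step`` apart. Junction points shared between segments are emitted
    once.

    Parameters
    ----------
    tree:
        Tree to resample.
    step:
        Maximum spacing between consecutive points, in voxels.
    return_nodes:
        If True, also return the id of the child node of the segment each
        point was sampled from (the root maps to its own id), for carrying
        per-node attributes (e.g. neurite type) onto resampled points.

    Returns
    -------
    (N, 3) float array of points in (x, y, z) order; optionally an (N,) int
    array of source node ids.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if tree.is_empty:
        pts = np.zeros((0, 3))
        return (pts, np.zeros(0, dtype=int)) if return_nodes else pts
    points: list[np.ndarray] = [tree.root.xyz]
    sources: list[int] = [tree.root.id]
    for parent, child in tree.segments():
        a, b = parent.xyz, child.xyz
        length = float(np.linalg.norm(b - a))
        n_seg = max(1, int(np.ceil(length / step)))
        # skip t=0: the parent endpoint is emitted by its own segment (or root)
        ts = np.arange(1, n_seg + 1) / n_seg
        for t in ts:
            points.append(a + t * (b - a))
            sources.append(child.id)
    pts = np.asarray(points)
    if return_nodes:
        return pts, np.asarray(sources, dtype=int)
    return pts
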