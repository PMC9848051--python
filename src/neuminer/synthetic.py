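"""Synthetic fMOST-like neurite phantoms.

Whole-brain fluorescence micro-optical sectioning tomography (fMOST) crops
of single neurons share a recognizable statistical structure: sparse
branching tubular fibers of roughly one-voxel radius over a dark background,
a bright soma, Gaussian-looking sensor noise, occasional oval plaque
artifacts, and a strongly bimodal fiber intensity distribution -- bright
dendrites and proximal axons versus "weak fibers" whose voxel values sit
below ~20 on the 8-bit scale. Manual annotations are partial: a fraction of
the fibers visible in the image is absent from the label.

This module generates seeded (image, gold-standard tree, labeled subtree)
triplets with exactly those features so that enhancement, segmentation,
tracing and evaluation can all be exercised end to end without external
data. Weak fibers are written with SWC type 2 (axon) and strong fibers with
type 3 (dendrite), mirroring the biological association between weak signal
and axons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .swc import SwcNode, SwcTree, write_swc, SOMA_TYPE, AXON_TYPE, DENDRITE_TYPE

__all__ = [
    "FiberSpec",
    "SceneConfig",
    "Scene",
    "generate_tree",
    "make_fiber_specs",
    "render_volume",
    "add_artifacts",
    "make_partial_labels",
    "generate_scene",
    "write_scene",
]

#: default weak-fiber threshold: raw value 20 on the 8-bit scale
WEAK_THRESHOLD = 20.0 / 255.0


@dataclass(frozen=True)
class FiberSpec:
    """One unbranched fiber chain to render as a tube.

    ``centerline`` is an ordered (N, 3) array of (x, y, z) voxel coordinates
    with consecutive points at most 1.5 voxels apart; ``peak_intensity`` is
    the tube's centerline brightness on the normalized [0, 1] scale.
    """

    centerline: np.ndarray
    radius: float
    peak_intensity: float
    labeled: bool = True

    def __post_init__(self):
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[1] != 3 or len(cl) < 2:
            raise ValueError("centerline must be an (N>=2, 3) array")
        gaps = np.linalg.norm(np.diff(cl, axis=0), axis=1)
        if gaps.max() > 1.5 + 1e-9:
            raise ValueError("consecutive centerline points must be <= 1.5 apart")
        if not 0 < self.peak_intensity <= 1:
            raise ValueError("peak_intensity must be in (0, 1]")
        object.__setattr__(self, "centerline", cl)


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene; every value has a fixed default
    chosen to emulate a down-sampled single-neuron fMOST crop.

    Intensities are on the normalized [0, 1] scale; the canonical raw
    weak-fiber threshold 20 maps to 20/255 at 8-bit depth.
    """

    volume_shape: tuple[int, int, int] = (48, 64, 64)  # (z, y, x)
    n_fibers: int = 6
    weak_fraction: float = 0.5
    weak_intensity_range: tuple[float, float] = (0.045, 0.078)
    strong_intensity_range: tuple[float, float] = (0.25, 0.7)
    background_mean: float = 0.02
    noise_sigma: float = 0.015
    n_plaques: int = 2
    unlabeled_fraction: float = 0.25
    soma_position: tuple[float, float, float] | None = None  # (x, y, z)
    rng_seed: int = 0
    # fiber geometry
    step_length: float = 1.0
    max_turn_deg: float = 30.0
    branch_prob: float = 0.04
    radius_range: tuple[float, float] = (0.6, 1.2)
    soma_radii_xyz: tuple[float, float, float] = (6.0, 6.0, 3.0)
    weak_threshold: float = WEAK_THRESHOLD

    def __post_init__(self):
        if not (0 <= self.weak_fraction <= 1 and 0 <= self.unlabeled_fraction <= 1):
            raise ValueError("weak_fraction and unlabeled_fraction must be in [0,1]")
        for lo, hi in (self.weak_intensity_range, self.strong_intensity_range):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("intensity ranges must lie within [0,1]")
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")

    @property
    def soma_xyz(self) -> np.ndarray:
        if self.soma_position is not None:
            return np.asarray(self.soma_position, dtype=float)
        nz, ny, nx = self.volume_shape
        return np.array([nx / 2, ny / 2, nz / 2])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Scene:
    """One generated scene: image plus full and partial gold standards."""

    image: np.ndarray
    gold: SwcTree
    labeled: SwcTree
    clean_image: np.ndarray = field(repr=False, default=None)
    fibers: list[FiberSpec] = field(repr=False, default=None)

    def __iter__(self):
        return iter((self.image, self.gold, self.labeled))


def _rng(cfg: SceneConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per generation stage
    return np.random.default_rng([int(cfg.rng_seed) % (2**31), stream])


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _turn(direction: np.ndarray, max_deg: float, rng) -> np.ndarray:
    """Rotate ``direction`` by a random angle <= max_deg about a random axis."""
    theta = np.deg2rad(rng.uniform(0, max_deg))
    # random unit vector orthogonal to direction
    u = _random_unit(rng)
    u -= u.dot(direction) * direction
    n = np.linalg.norm(u)
    if n < 1e-8:
        return direction
    u /= n
    return np.cos(theta) * direction + np.sin(theta) * u


def generate_tree(cfg: SceneConfig) -> SwcTree:
    """Grow a single-soma tree of bounded-curvature random-walk fibers.

    Each of ``cfg.n_fibers`` primary fibers starts at the soma with a random
    direction and advances in unit steps, turning at most ``max_turn_deg``
    per step; side branches spawn with probability ``branch_prob`` per step.
    Fibers stop at the volume margin. Deterministic given ``rng_seed``.
    """
    nz, ny, nx = cfg.volume_shape
    if min(nz, ny, nx) < 12 and cfg.n_fibers > 0:
        raise ValueError(
            f"volume {cfg.volume_shape} too small to place fibers (min dim 12)"
        )
    rng = _rng(cfg, 0)
    soma = cfg.soma_xyz
    lo = np.array([1.0, 1.0, 1.0])
    hi = np.array([nx - 2.0, ny - 2.0, nz - 2.0])
    if np.any(soma < lo) or np.any(soma > hi):
        raise ValueError("soma must lie inside the volume")
    nodes = [SwcNode(1, SOMA_TYPE, soma[0], soma[1], soma[2],
                     max(cfg.soma_radii_xyz), -1)]
    next_id = 2
    diag = float(np.linalg.norm([nx, ny, nz]))
    for _ in range(cfg.n_fibers):
        radius = rng.uniform(*cfg.radius_range)
        direction = _random_unit(rng)
        budget = int(rng.uniform(0.35, 0.6) * diag)
        # stack of (parent_id, position, direction, remaining steps)
        stack = [(1, soma.copy(), direction, budget)]
        while stack:
            parent_id, pos, direction, remaining = stack.pop()
            while remaining > 0:
                direction = _turn(direction, cfg.max_turn_deg, rng)
                new = pos + cfg.step_length * direction
                if np.any(new < lo) or np.any(new > hi):
                    break
                type_code = AXON_TYPE  # placeholder, fixed by weak/strong split
                nodes.append(SwcNode(next_id, type_code,
                                     new[0], new[1], new[2], radius, parent_id))
                parent_id, pos = next_id, new
                next_id += 1
                remaining -= 1
                if remaining > 3 and rng.random() < cfg.branch_prob:
                    bdir = _turn(direction, 60.0, rng)
                    split = remaining // 2
                    stack.append((parent_id, pos.copy(), bdir, split))
                    remaining -= split
    # weak/strong assignment per primary fiber, encoded in the type code
    tree = SwcTree(nodes)
    primaries = [c.id for c in tree.children(1)]
    n_weak = int(round(cfg.weak_fraction * len(primaries)))
    weak_ids = set(np.array(primaries, dtype=int)[
        _rng(cfg, 1).permutation(len(primaries))[:n_weak]
    ]) if primaries else set()
    typed = []
    for n in tree:
        if n.id == 1:
            typed.append(n)
            continue
        # find this node's primary fiber (child-of-soma ancestor)
        a = n
        while a.parent_id != 1:
            a = tree.node(a.parent_id)
        code = AXON_TYPE if a.id in weak_ids else DENDRITE_TYPE
        typed.append(SwcNode(n.id, code, n.x, n.y, n.z, n.radius, n.parent_id))
    return SwcTree(typed)


def make_fiber_specs(tree: SwcTree, cfg: SceneConfig) -> list[FiberSpec]:
    """Split a generated tree into unbranched chains with peak intensities.

    All chains of one primary fiber share that fiber's peak, drawn from the
    weak or strong range according to the type code the generator assigned.
    """
    rng = _rng(cfg, 2)
    if tree.is_empty or len(tree) == 1:
        return []
    peaks: dict[int, float] = {}
    for child in tree.children(tree.root.id):
        lohi = (cfg.weak_intensity_range if child.type_code == AXON_TYPE
                else cfg.strong_intensity_range)
        peaks[child.id] = float(rng.uniform(*lohi))

    def primary_of(node):
        a = node
        while a.parent_id != tree.root.id:
            a = tree.node(a.parent_id)
        return a.id

    specs: list[FiberSpec] = []
    # chains start at soma children and at every branch point child
    starts = list(tree.children(tree.root.id))
    for n in tree:
        if n.id != tree.root.id and len(tree.children(n.id)) > 1:
            starts.extend(tree.children(n.id))
    seen = set()
    for start in starts:
        if start.id in seen:
            continue
        chain = [tree.node(start.parent_id).xyz, start.xyz]
        seen.add(start.id)
        cur = start
        while True:
            kids = tree.children(cur.id)
            if len(kids) != 1:
                break
            cur = kids[0]
            chain.append(cur.xyz)
            seen.add(cur.id)
        specs.append(FiberSpec(
            centerline=np.asarray(chain),
            radius=float(start.radius),
            peak_intensity=peaks[primary_of(start)],
        ))
    return specs


def _splat_tube(vol: np.ndarray, spec: FiberSpec) -> None:
    """Draw one tube with a Gaussian radial profile, max-accumulated.

    The radial sigma combines the geometric tube width (radius / 1.5) with a
    fixed 0.7-voxel point-spread/voxel-integration term, so even sub-voxel
    fibers light up the voxel lattice the way diffraction-blurred
    light-microscopy neurites do. The profile is truncated at 3 sigma.
    """
    nz, ny, nx = vol.shape
    sigma = float(np.hypot(spec.radius / 1.5, 0.7))
    reach = int(np.ceil(3 * sigma))
    cl = spec.centerline
    # oversample the polyline so tube cross-sections overlap
    fine = [cl[0]]
    for a, b in zip(cl[:-1], cl[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(seg / 0.5)))
        for t in np.arange(1, n + 1) / n:
            fine.append(a + t * (b - a))
    for x, y, z in fine:
        xi, yi, zi = int(round(x)), int(round(y)), int(round(z))
        zs = slice(max(zi - reach, 0), min(zi + reach + 1, nz))
        ys = slice(max(yi - reach, 0), min(yi + reach + 1, ny))
        xs = slice(max(xi - reach, 0), min(xi + reach + 1, nx))
        zz, yy, xx = np.mgrid[zs, ys, xs]
        d2 = (xx - x) ** 2 + (yy - y) ** 2 + (zz - z) ** 2
        patch = spec.peak_intensity * np.exp(-d2 / (2 * sigma**2))
        np.maximum(vol[zs, ys, xs], patch, out=vol[zs, ys, xs])


def render_volume(tree: SwcTree, fibers: list[FiberSpec],
                  cfg: SceneConfig) -> np.ndarray:
    """Render fibers and soma over a flat background; noise-free, in [0, 1].

    Tubes are max-accumulated (fluorescence from one neurite does not add
    with itself at junctions); the soma is a bright super-Gaussian ellipsoid.
    """
    nz, ny, nx = cfg.volume_shape
    vol = np.full((nz, ny, nx), float(cfg.background_mean))
    for spec in fibers:
        _splat_tube(vol, spec)
    if not tree.is_empty:
        sx, sy, sz = cfg.soma_xyz
        rx, ry, rz = cfg.soma_radii_xyz
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        d2 = ((xx - sx) / rx) ** 2 + ((yy - sy) / ry) ** 2 + ((zz - sz) / rz) ** 2
        np.maximum(vol, 0.95 * np.exp(-(d2**2)), out=vol)
    return np.clip(vol, 0.0, 1.0)


def add_artifacts(vol: np.ndarray, cfg: SceneConfig,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Add i.i.d. Gaussian noise and smooth oval plaque artifacts.

    Plaques are random ellipsoids of smoothly elevated intensity that mimic
    the autofluorescent blobs seen in real brain crops. Output clipped to
    [0, 1]; with ``noise_sigma=0`` and ``n_plaques=0`` the input is returned
    unchanged.
    """
    if vol.min() < 0 or vol.max() > 1:
        raise ValueError("input volume must be in [0, 1]")
    if rng is None:
        rng = _rng(cfg, 3)
    out = np.asarray(vol, dtype=np.float64).copy()
    nz, ny, nx = out.shape
    for _ in range(cfg.n_plaques):
        cx = rng.uniform(5, nx - 5)
        cy = rng.uniform(5, ny - 5)
        cz = rng.uniform(3, nz - 3)
        rx, ry = rng.uniform(2.5, 6.0, size=2)
        rz = rng.uniform(1.5, 3.5)
        amp = rng.uniform(0.08, 0.2)
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        d2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2
        out += amp * np.exp(-(d2**2))
    if cfg.noise_sigma > 0:
        out += rng.normal(0.0, cfg.noise_sigma, size=out.shape)
    if cfg.n_plaques == 0 and cfg.noise_sigma == 0:
        return out
    return np.clip(out, 0.0, 1.0)


def make_partial_labels(tree: SwcTree, cfg: SceneConfig) -> tuple[SwcTree, SwcTree]:
    """Delete random branch subtrees so only part of the neuron is annotated.

    Returns ``(labeled_subtree, full_tree)``. Candidate deletions are the
    subtrees hanging off the soma and off every branch point; they are
    removed in random order until the deleted cable length approximates
    ``unlabeled_fraction`` of the total. The soma always stays, and the
    labeled subtree remains connected.
    """
    if tree.is_empty or len(tree) == 1 or cfg.unlabeled_fraction == 0:
        return tree, tree
    rng = _rng(cfg, 4)
    total = tree.total_length()
    target = cfg.unlabeled_fraction * total

    candidates = [c.id for c in tree.children(tree.root.id)]
    for n in tree:
        if n.id != tree.root.id and len(tree.children(n.id)) > 1:
            candidates.extend(c.id for c in tree.children(n.id))
    order = rng.permutation(len(candidates))

    dropped: set[int] = set()
    dropped_len = 0.0

    def subtree_length(root_id):
        # cable length of the not-yet-dropped part, incl. the anchor edge
        ids = tree.subtree_ids(root_id) - dropped
        length = 0.0
        for p, c in tree.segments():
            if c.id in ids:
                length += float(np.linalg.norm(p.xyz - c.xyz))
        return length

    for i in order:
        cid = candidates[i]
        if cid in dropped:
            continue
        if dropped_len >= target:
            break
        length = subtree_length(cid)
        # accept if it moves the deleted length closer to the target
        if abs(dropped_len + length - target) <= abs(dropped_len - target):
            dropped |= tree.subtree_ids(cid)
            dropped_len += length
    labeled = tree.without(dropped)
    return labeled, tree


def generate_scene(cfg: SceneConfig) -> Scene:
    """Compose tree growth, rendering, artifacts and partial labeling.

    Fully deterministic for a given config (including seed). The returned
    :class:`Scene` iterates as ``(image, gold, labeled)`` and additionally
    carries the noise-free image and the fiber specs for bookkeeping.
    """
    tree = generate_tree(cfg)
    fibers = make_fiber_specs(tree, cfg)
    clean = render_volume(tree, fibers, cfg)
    image = add_artifacts(clean, cfg)
    labeled, gold = make_partial_labels(tree, cfg)
    return Scene(image=image, gold=gold, labeled=labeled,
                 clean_image=clean, fibers=fibers)


def write_scene(scene: Scene, outdir: str | Path, cfg: SceneConfig | None = None,
                bit_depth: int = 8) -> None:
    """Write a scene as image.tif (multi-page, one page per z-slice),
    gold.swc, labeled.swc and, if given, config.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    maxval = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    raw = np.rint(scene.image * maxval).astype(dtype)
    tifffile.imwrite(outdir / "image.tif", raw)
    write_swc(scene.gold, outdir / "gold.swc")
    write_swc(scene.labeled, outdir / "labeled.swc")
    if cfg is not None:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh)
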