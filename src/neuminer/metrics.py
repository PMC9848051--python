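"""Reconstruction-versus-gold evaluation metrics.

The workhorse distances are the classic asymmetric spatial-distance family
computed on trees resampled to ~1-voxel point spacing:

* **SD** (spatial distance): mean over points of one tree of the distance to
  the nearest point of the other.
* **SSD** (substantial SD): the same mean restricted to distances larger
  than a threshold (2 voxels), ignoring sub-voxel jitter.
* **PDS** (percentage of different structure): the fraction of points whose
  nearest distance exceeds that threshold.

Each comes in a gold-to-reconstruction direction (``*12``, recall-like), a
reconstruction-to-gold direction (``*21``, precision-like) and their average.
Lower is better for all of them.

Also provided: intensity-stratified recall (how well weak fibers are
recovered as a function of image brightness), total-cable path-length ratio,
and a self-crossing statistic that counts pairs of topologically distant
nodes passing within a small Euclidean distance -- a driver of over-tracing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .swc import SwcTree, resample_tree
from .synthetic import WEAK_THRESHOLD

__all__ = [
    "MetricsReport",
    "nearest_distances",
    "sd_metrics",
    "ssd_metrics",
    "pds_metrics",
    "recall_by_intensity",
    "path_length_ratio",
    "self_crossing_count",
    "evaluate_pair",
]

DISTANCE_THRESHOLD = 2.0  # voxels, for SSD / PDS / recall matching


@dataclass
class MetricsReport:
    """All pairwise metrics for one (gold, reconstruction) pair."""

    sd12: float
    sd21: float
    sd: float
    ssd12: float
    ssd21: float
    ssd: float
    pds12: float
    pds21: float
    pds: float
    path_length_ratio: float
    recall_by_intensity: dict[str, float] = field(default_factory=dict)
    weak_recall: float = float("nan")
    n_self_crossings: int = -1

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "sd12", "sd21", "sd", "ssd12", "ssd21", "ssd",
            "pds12", "pds21", "pds", "path_length_ratio", "weak_recall",
            "n_self_crossings")}
        d["recall_by_intensity"] = dict(self.recall_by_intensity)
        return d


def nearest_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """For each point of ``a``, the Euclidean distance to its nearest
    neighbor in ``b``. Both arrays are (N, 3); ``b`` must be nonempty."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(b) == 0:
        raise ValueError("cannot compute nearest distances to an empty set")
    if len(a) == 0:
        return np.zeros(0)
    dists, _ = cKDTree(b).query(a)
    return dists


def _tree_points(tree: SwcTree, resample: bool, step: float) -> np.ndarray:
    if tree.is_empty:
        raise ValueError("metrics need nonempty trees")
    return resample_tree(tree, step=step) if resample else tree.coordinates()


def sd_metrics(gold: SwcTree, recon: SwcTree, resample: bool = True,
               step: float = 1.0) -> tuple[float, float, float]:
    """(sd12, sd21, sd): gold-to-recon, recon-to-gold mean nearest distance,
    and their average."""
    g = _tree_points(gold, resample, step)
    r = _tree_points(recon, resample, step)
    sd12 = float(nearest_distances(g, r).mean())
    sd21 = float(nearest_distances(r, g).mean())
    return sd12, sd21, (sd12 + sd21) / 2


def _substantial(dists: np.ndarray, thresh: float) -> float:
    big = dists[dists > thresh]
    return float(big.mean()) if len(big) else 0.0


def ssd_metrics(gold: SwcTree, recon: SwcTree, thresh: float = DISTANCE_THRESHOLD,
                resample: bool = True, step: float = 1.0):
    """Mean of nearest distances larger than ``thresh`` (0 if none exceed)."""
    g = _tree_points(gold, resample, step)
    r = _tree_points(recon, resample, step)
    ssd12 = _substantial(nearest_distances(g, r), thresh)
    ssd21 = _substantial(nearest_distances(r, g), thresh)
    return ssd12, ssd21, (ssd12 + ssd21) / 2


def pds_metrics(gold: SwcTree, recon: SwcTree, thresh: float = DISTANCE_THRESHOLD,
                resample: bool = True, step: float = 1.0):
    """Fraction of points whose nearest distance exceeds ``thresh``."""
    g = _tree_points(gold, resample, step)
    r = _tree_points(recon, resample, step)
    pds12 = float((nearest_distances(g, r) > thresh).mean())
    pds21 = float((nearest_distances(r, g) > thresh).mean())
    return pds12, pds21, (pds12 + pds21) / 2


def recall_by_intensity(
    gold: SwcTree,
    recon: SwcTree,
    image: np.ndarray,
    bins=None,
    match_radius: float = DISTANCE_THRESHOLD,
    weak_threshold: float = WEAK_THRESHOLD,
    step: float = 1.0,
):
    """Recall of resampled gold points, stratified by image intensity.

    A gold point counts as traced when its nearest reconstruction point lies
    within ``match_radius`` voxels. Each point's intensity is the (in [0,1]
    normalized) image value at its nearest voxel. Returns ``(per_bin,
    weak_recall)`` where ``per_bin`` maps a "lo-hi" raw-8-bit-scale edge
    label to the recall in that bin (NaN for empty bins) and ``weak_recall``
    is the recall over points below ``weak_threshold``.
    """
    if bins is None:
        bins = np.array([0, weak_threshold, 40 / 255, 80 / 255, 160 / 255, 1.0001])
    bins = np.asarray(bins, dtype=float)
    g = resample_tree(gold, step=step)
    r = _tree_points(recon, True, step)
    vox = np.rint(g).astype(int)  # (x, y, z)
    nz, ny, nx = image.shape
    inside = ((vox >= 0).all(1) & (vox[:, 0] < nx) & (vox[:, 1] < ny)
              & (vox[:, 2] < nz))
    if not inside.all():
        raise ValueError("gold points fall outside the image volume")
    intens = image[vox[:, 2], vox[:, 1], vox[:, 0]]
    traced = nearest_distances(g, r) <= match_radius
    per_bin: dict[str, float] = {}
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = (intens >= lo) & (intens < hi)
        label = f"{lo * 255:.0f}-{hi * 255:.0f}"
        per_bin[label] = float(traced[sel].mean()) if sel.any() else float("nan")
    weak_sel = intens < weak_threshold
    weak_recall = float(traced[weak_sel].mean()) if weak_sel.any() else float("nan")
    return per_bin, weak_recall


def voxel_recall(
    gold: SwcTree,
    prob: np.ndarray,
    image: np.ndarray | None = None,
    prob_threshold: float = 0.5,
    weak_threshold: float = WEAK_THRESHOLD,
    neighborhood_xyz=(3, 3, 1),
    step: float = 1.0,
) -> dict[str, float]:
    """Segmentation-level recall of gold points against a probability map.

    A resampled gold point counts as segmented when the maximum probability
    over its fiber-width neighborhood (default the 3 x 3 x 1 label stamp)
    reaches ``prob_threshold``. With ``image`` given, recall is also split
    into weak (< ``weak_threshold``) and strong points by the image value at
    each gold point. Returns {"overall", "weak", "strong"} (NaN for empty
    strata).
    """
    g = resample_tree(gold, step=step)
    vox = np.rint(g).astype(int)
    nz, ny, nx = prob.shape
    hx, hy, hz = (int(n) // 2 for n in neighborhood_xyz)
    hits = np.zeros(len(vox), dtype=bool)
    for i, (x, y, z) in enumerate(vox):
        patch = prob[max(z - hz, 0): z + hz + 1,
                     max(y - hy, 0): y + hy + 1,
                     max(x - hx, 0): x + hx + 1]
        hits[i] = patch.size > 0 and patch.max() >= prob_threshold
    out = {"overall": float(hits.mean()) if len(hits) else float("nan"),
           "weak": float("nan"), "strong": float("nan")}
    if image is not None:
        intens = image[np.clip(vox[:, 2], 0, nz - 1),
                       np.clip(vox[:, 1], 0, ny - 1),
                       np.clip(vox[:, 0], 0, nx - 1)]
        weak = intens < weak_threshold
        if weak.any():
            out["weak"] = float(hits[weak].mean())
        if (~weak).any():
            out["strong"] = float(hits[~weak].mean())
    return out


def path_length_ratio(gold: SwcTree, recon: SwcTree) -> float:
    """Total cable length of the reconstruction relative to the gold standard."""
    gl = gold.total_length()
    if gl == 0:
        raise ValueError("gold standard has zero cable length")
    return recon.total_length() / gl


def _ancestors_within(tree: SwcTree, node_id: int, generations: int) -> set[int]:
    out = {node_id}
    cur = tree.node(node_id)
    for _ in range(generations):
        if cur.parent_id == -1:
            break
        cur = tree.node(cur.parent_id)
        out.add(cur.id)
    return out


def self_crossing_count(
    tree: SwcTree,
    soma_exclusion: float = 50.0,
    generation_exclusion: int = 10,
    dist_thresh: float = 1.0,
    crop=None,
) -> int:
    """Count node pairs closer than ``dist_thresh`` that are topologically
    unrelated: both farther than ``soma_exclusion`` voxels from the root and
    not sharing an ancestor within ``generation_exclusion`` generations.
    ``crop`` optionally restricts to a ((x0,x1),(y0,y1),(z0,z1)) box.
    """
    if tree.is_empty:
        return 0
    root_xyz = tree.root.xyz
    nodes = [n for n in tree
             if np.linalg.norm(n.xyz - root_xyz) >= soma_exclusion]
    if crop is not None:
        (x0, x1), (y0, y1), (z0, z1) = crop
        nodes = [n for n in nodes
                 if x0 <= n.x < x1 and y0 <= n.y < y1 and z0 <= n.z < z1]
    if len(nodes) < 2:
        return 0
    pts = np.array([n.xyz for n in nodes])
    ids = [n.id for n in nodes]
    anc = {nid: _ancestors_within(tree, nid, generation_exclusion) for nid in ids}
    pairs = cKDTree(pts).query_pairs(dist_thresh)
    count = 0
    for i, j in pairs:
        if anc[ids[i]].isdisjoint(anc[ids[j]]):
            count += 1
    return count


def evaluate_pair(
    gold: SwcTree,
    recon: SwcTree,
    image: np.ndarray | None = None,
    thresh: float = DISTANCE_THRESHOLD,
    match_radius: float = DISTANCE_THRESHOLD,
    weak_threshold: float = WEAK_THRESHOLD,
    resample: bool = True,
    crossing_kwargs: dict | None = None,
) -> MetricsReport:
    """All metrics for one pair; intensity-stratified recall needs ``image``."""
    sd12, sd21, sd = sd_metrics(gold, recon, resample=resample)
    ssd12, ssd21, ssd = ssd_metrics(gold, recon, thresh=thresh, resample=resample)
    pds12, pds21, pds = pds_metrics(gold, recon, thresh=thresh, resample=resample)
    report = MetricsReport(
        sd12=sd12, sd21=sd21, sd=sd,
        ssd12=ssd12, ssd21=ssd21, ssd=ssd,
        pds12=pds12, pds21=pds21, pds=pds,
        path_length_ratio=path_length_ratio(gold, recon),
    )
    if image is not None:
        per_bin, weak = recall_by_intensity(
            gold, recon, image, match_radius=match_radius,
            weak_threshold=weak_threshold)
        report.recall_by_intensity = per_bin
        report.weak_recall = weak
    kwargs = crossing_kwargs if crossing_kwargs is not None else {}
    report.n_self_crossings = self_crossing_count(recon, **kwargs)
    return report
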