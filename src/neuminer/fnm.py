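"""Online false-negative mining (FNM).

Weak fibers are the dominant source of false negatives in neurite
segmentation: they are labeled foreground but the network, early in
training and often forever after, scores them below 0.5. FNM re-weights the
per-voxel loss on exactly those voxels, recomputed on the fly from the
current prediction at every iteration:

    FN = F  ∩  {P < 0.5}
    w(v) = w_FN  if v in FN  else  1.0

with ``w_FN = 1.5``. Only false negatives are up-weighted -- annotations
are partial, so an apparent false positive may well be an unlabeled fiber
and must not be punished harder. The weighted loss is the plain mean over
all N = B*C*Z*Y*X voxels of ``w * loss`` (divisor N, not the weight sum).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DEFAULT_WFN",
    "extract_false_negatives",
    "build_weight_map",
    "weighted_voxel_loss",
]

DEFAULT_WFN = 1.5


def extract_false_negatives(foreground: np.ndarray,
                            probability: np.ndarray) -> np.ndarray:
    """Boolean mask of false-negative voxels: labeled foreground with
    predicted foreground probability below 0.5.

    No gradient flows through this mask; it is a detached, per-iteration
    statistic of the current prediction.
    """
    foreground = np.asarray(foreground)
    probability = np.asarray(probability)
    if foreground.shape != probability.shape:
        raise ValueError(
            f"shape mismatch: label {foreground.shape} vs "
            f"prediction {probability.shape}")
    if probability.size and (probability.min() < 0 or probability.max() > 1):
        raise ValueError("probabilities must be in [0, 1]")
    return (foreground > 0) & (probability < 0.5)


def build_weight_map(fn_mask: np.ndarray, wfn: float = DEFAULT_WFN) -> np.ndarray:
    """Per-voxel loss weights: ``wfn`` on false negatives, 1.0 elsewhere."""
    if wfn < 1.0:
        raise ValueError("wfn must be >= 1: only false negatives are up-weighted")
    return np.where(np.asarray(fn_mask, dtype=bool), np.float32(wfn),
                    np.float32(1.0))


def weighted_voxel_loss(per_voxel_losses: np.ndarray,
                        weights: np.ndarray) -> float:
    """Mean over all voxels of weight * loss (divisor is the voxel count N)."""
    losses = np.asarray(per_voxel_losses)
    weights = np.asarray(weights)
    if losses.shape != weights.shape:
        raise ValueError("losses and weights must have the same shape")
    return float(np.mean(weights * losses))
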