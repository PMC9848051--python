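"""Generate one synthetic fMOST-like scene and look at its statistics.

The generator grows a branching neuron from a central soma, renders it as
Gaussian tubes over a dark background, adds noise and plaque artifacts, and
deletes a fraction of the branches from the annotation to emulate partial
labeling.
"""

import numpy as np

from neuminer import SceneConfig, generate_scene, WEAK_THRESHOLD
from neuminer.swc import AXON_TYPE, resample_tree

cfg = SceneConfig(rng_seed=7)
scene = generate_scene(cfg)

print(f"volume shape (z,y,x): {scene.image.shape}")
print(f"gold nodes: {len(scene.gold)}, labeled nodes: {len(scene.labeled)} "
      f"({scene.labeled.total_length() / scene.gold.total_length():.0%} "
      f"of cable length annotated)")

pts = resample_tree(scene.gold)
vox = np.rint(pts).astype(int)
intens = scene.image[vox[:, 2], vox[:, 1], vox[:, 0]]
weak = intens < WEAK_THRESHOLD
print(f"gold centerline points: {len(pts)}, weak (<20/255): {weak.mean():.0%}")
print(f"background level ~{np.median(scene.image):.3f}, "
      f"image max {scene.image.max():.3f}")
n_weak_fibers = sum(1 for c in scene.gold.children(scene.gold.root.id)
                    if c.type_code == AXON_TYPE)
print(f"weak primary fibers: {n_weak_fibers} of "
      f"{len(scene.gold.children(scene.gold.root.id))}")
# Weak fibers sit barely above background -- the tracing challenge this
# package exists for.
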