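"""Rasterize a gold-standard reconstruction into a training label volume.

Each resampled centerline point is stamped with a 3 x 3 x 1 voxel element
(microscopes resolve x-y finer than z) and the soma gets a fixed
18 x 18 x 6 cuboid painted into both the label and the image.
"""

from neuminer import (SceneConfig, generate_scene, make_label_volume,
                      rasterize_tree, soma_mask, paint_soma)

scene = generate_scene(SceneConfig(rng_seed=3))
shape = scene.image.shape

fibers = rasterize_tree(scene.labeled, shape)
soma = soma_mask(scene.labeled, shape)
label = make_label_volume(scene.labeled, shape)
image = paint_soma(scene.image, scene.labeled)

print(f"fiber voxels: {int(fibers.sum())}")
print(f"soma cuboid voxels: {int(soma.sum())} (18*18*6 = {18 * 18 * 6})")
print(f"label foreground: {int(label.sum())} voxels "
      f"({label.mean():.2%} of the volume)")
print(f"soma painted into image at intensity {image.max():.2f}")
# Foreground is sparse -- under 2% of voxels -- which is why dice loss and
# false-negative mining matter.
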