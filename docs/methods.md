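# Methods

## Problem

Whole-brain light microscopy (fMOST-class imaging) resolves single neurons
at sub-micron resolution, but a large share of neurite signal — mostly
axonal — is *weak*: voxel values below ~20 on the 8-bit scale, barely above
background. Classical tracers binarize on intensity and systematically drop
these fibers. This package implements a segmentation-assisted tracing
module built from four parts:

1. **DTGT** — a derivative-truncated gamma transform that amplifies weak
   signal without the halo artifact of plain gamma correction;
2. **FNM** — online false-negative mining in the segmentation loss;
3. **fusion** — a convex combination of the image and the network's
   foreground probability, handed to a tracer;
4. **evaluation** — the SD/SSD/PDS spatial-distance family plus
   intensity-stratified recall and a self-crossing statistic.

A synthetic phantom generator reproduces the statistical structure of
single-neuron fMOST crops so every stage is testable without the
multi-terabyte source data.

## DTGT

With intensities normalized to [0, 1], plain gamma is g(x) = x^γ, γ < 1.
Its derivative γ·x^(γ−1) falls below 1 for x above the truncation point

    δ = exp(ln γ / (1 − γ)) = γ^(1/(1−γ)),   γ·δ^(γ−1) = 1,

so bright-region contrast is compressed (the "halo"). DTGT keeps the gamma
curve on [0, δ] and continues with the unit-slope identity above:

    ĝ(x) = x^γ           x ≤ δ
         = x − δ + δ^γ   x > δ

then divides by ĝ(1) = 1 − δ + δ^γ so the range is again [0, 1]. The
divisor is a constant of the transform, not a data statistic: a per-volume
min-max rescale would silently reintroduce data-dependent contrast
compression. ĝ is continuous at δ, strictly increasing, and its
pre-standardization slope is ≥ 1 everywhere; γ = 1 is the exact identity.
Default γ = 0.4 (illustrative value in the source work; the effective
pipeline value is configurable).

## Label generation

Gold standards are SWC trees in voxel units (0-based voxel-center
coordinates; arrays are (z, y, x), sizes quoted (x, y, z)). Labels are
produced by resampling every parent→child segment at ≤ 1 voxel spacing
(endpoints included), rounding to the nearest voxel and stamping a
3 × 3 × 1 (x, y, z) element — z is not dilated because axial resolution is
coarser. The soma is overlaid with an 18 × 18 × 6 cuboid in both the label
and the training image (painted at the image maximum by default; the
original description does not state the painted intensity). Even-sized
cuboids cannot be voxel-symmetric; we anchor them as floor-centered
half-open ranges [c − s/2, c + s/2), which keeps exactly s voxels per axis
when unclipped. An inscribed-ellipsoid soma is available as an option and
behaves similarly. Node radii from the SWC are carried through I/O but
ignored for labels (uniform fiber width by design).

## Segmentation network and training

A plain 3D encoder–decoder with skip connections: two 3³ convolutions per
level, instance normalization before every leaky-ReLU, 2× max pooling,
nearest-neighbor upsampling followed by a 1×1×1 channel-reducing
convolution (the decoder block's 3³ convolutions do the spatial
smoothing). Two 1×1×1 heads emit 2-channel logits for deep supervision:
the final block at full resolution (weight 1.0) and the preceding block at
half resolution (weight 0.5), the latter scored against a max-pooled label
so single-voxel fibers survive downsampling. With only two levels the
half-resolution head sits on the bottleneck.

The network, losses and optimizer are implemented directly in numpy with
explicit backward passes (convolution as im2col GEMMs); gradients are
verified against finite differences in float64 in the test suite.
Full-scale defaults mirror standard practice for this architecture:
Nesterov SGD, initial learning rate 0.01, momentum 0.99, weight decay
3e−5, polynomial decay power 0.9, 15 200 iterations, 160 × 160 × 128
(x, y, z) crops, w_FN = 1.5. Augmentation: per-axis flips (p = 0.5), gamma
jitter γ ∈ [0.7, 1.4] (p = 0.3), Gaussian noise σ ≤ 0.05 (p = 0.3),
isotropic resize 0.8–1.2× (p = 0.2); geometric ops are applied identically
to image and label with nearest-neighbor label resampling. The **tiny
profile** used by all CPU tests is a 2-level, 8-channel network on 32³
crops, batch 1, 200 iterations — sized so that the full six-run benchmark
(two w_FN values × three seeds) completes in minutes on a single core.

### False-negative mining

Per iteration the false-negative set is recomputed from the current
prediction: FN = F ∩ {P < 0.5}, where F is the label foreground and P the
foreground softmax of the final head (detached; no gradient flows through
the mask). The per-voxel weight is w_FN = 1.5 on FN and 1.0 elsewhere, and
the weighted loss is the mean over all N = B·C·Z·Y·X voxels of w·ℓ — the
divisor is N, not Σw, so up-weighting FN strictly increases the loss
whenever FN ≠ ∅ and changes nothing when the prediction is perfect.
Only false negatives are up-weighted: annotations are partial, so apparent
false positives are often unlabeled true fibers and must not be punished.
Weights apply to the cross-entropy term only; dice is a set-overlap
statistic rather than a per-voxel loss and is left unweighted (a weighted
dice variant exists behind a flag). The auxiliary head mines its own FN
mask at its own resolution against the pooled label.

## Fusion and tracing

The traced volume is x̂ = α·x + (1 − α)·p with α = 0.8, x the normalized
*original* image and p the foreground probability. The built-in tracer is
deliberately simple: threshold x̂ (default 0.15), keep the connected
component containing the soma, skeletonize in 3D, build the 26-connected
weighted voxel graph of the skeleton, and take the shortest-path spanning
tree rooted at the skeleton voxel nearest the soma. A soma voxel below
threshold raises an explicit disconnected-soma error. Production use would
export the fused volume and run an established tracer (e.g. APP2 in Vaa3D)
on it; the built-in extractor exists so the pipeline is end-to-end testable
here. The default threshold is chosen from the fusion arithmetic: with
α = 0.8, a weak fiber (x ≈ 0.05–0.08) crosses 0.15 only when the network
assigns it appreciable probability, while background (x ≈ 0.02, p ≈ 0)
stays far below.

## Metrics

Both trees are resampled to ≤ 1-voxel point spacing before distance
computation so "points" approximates "voxels" (`resample=False` gives
raw-node behavior). For point sets G (gold) and R (reconstruction):

* SD12 = mean over G of nearest-neighbor distance to R (recall-like);
  SD21 the reverse (precision-like); SD their average. Lower is better.
* SSD restricts the mean to distances > 2 voxels and is defined as 0 when
  none exceed the threshold (no "substantial" discrepancy).
* PDS is the fraction of points with nearest distance > 2 voxels.

Intensity-stratified recall marks a gold point traced when its nearest
reconstruction point is within 2 voxels (the SSD/PDS threshold; the match
radius is configurable and is this package's decision, not the source
work's), binning by image intensity; weak recall is the stratum below
20/255. Segmentation-level voxel recall marks a gold point segmented when
the maximum probability over its 3 × 3 × 1 stamp reaches 0.5. The
self-crossing count is the number of unordered node pairs within 1 voxel
of each other after excluding nodes < 50 voxels from the soma and pairs
sharing an ancestor within 10 generations; it is reported as a raw count
per tree (batch mode averages).

## Synthetic phantoms

Each scene is a (48, 64, 64) (z, y, x) volume with a central soma.
`n_fibers = 6` primary fibers grow from the soma as unit-step random walks
with per-step turning capped at 30° and branch probability 0.04; half the
fibers (weak_fraction = 0.5) get peak intensities drawn from
[0.045, 0.078] (below the 20/255 weak threshold; marked SWC type 2/axon)
and the rest from [0.25, 0.7] (type 3/dendrite). Tubes are rendered with a
Gaussian radial profile whose σ combines the geometric radius (r/1.5,
r ∈ [0.6, 1.2]) with a fixed 0.7-voxel point-spread/voxel-integration
term, max-accumulated, over a background of 0.02; the soma is a bright
super-Gaussian ellipsoid. Artifacts: i.i.d. Gaussian noise (σ = 0.015) and
two smooth elliptical plaques per scene. Partial labels delete random
branch subtrees (never the soma) until ~25% of cable length is unlabeled;
the labeled tree stays connected. Everything is deterministic per seed,
with independent seed streams per stage.

What the phantoms do **not** model: realistic optics (the PSF term is a
scalar blur, not a measured kernel), non-Gaussian sensor noise, multiple
somata, densely packed crossing neurons from *other* cells, intensity
falloff along a fiber, or annotation jitter. Passing tests therefore
demonstrate the machinery is correct and the method's qualitative behavior
(weak-fiber recall, ablation directions) under controlled conditions — not
performance on real brains.

## Numerical choices and degenerate inputs

* Losses are computed in float64 on float32 activations; ε = 1e−5 in dice,
  log-clipping at 1e−12 in cross-entropy.
* Instance-norm ε = 1e−5. Because normalization statistics are tile-local,
  tiled and whole-volume inference agree only approximately; the
  single-tile path is exact. Overlapping tiles are averaged uniformly.
* Nesterov update matches the common deep-learning convention
  (d = g + wd·p; v = μv + d; p ← p − lr·(d + μv)).
* Empty trees: resampling returns an empty list; metrics require nonempty
  trees; an SWC forest (multiple roots) is a parse error.
* SSD with no surviving distances returns 0, not NaN.
* A skeleton that vanishes (tiny blob) degrades to the soma voxel.
* Training is bit-reproducible for a fixed config on a fixed BLAS;
  w_FN = 1.0 is exactly the no-FNM baseline.

## Benchmark sizes

The default end-to-end benchmark trains the tiny profile on 8 scenes and
evaluates on 4 held-out scenes; the repository's acceptance script runs it
twice (w_FN 1.5 and 1.0) and the test suite six times (two w_FN values ×
three seeds). These sizes were chosen so the whole suite runs comfortably
on one CPU core while still exercising every stage at realistic sparsity.

## Known limitations

* The tiny 200-iteration schedule recovers strong fibers reliably but only
  a fraction of weak-fiber voxels; the FNM comparison is therefore
  directional (FNM ≥ baseline), not a reproduction of the full-scale
  recall gap.
* The built-in tracer has no pruning or gap-jumping; over- and
  under-tracing behavior of production tracers is out of scope.
* Fixed-width 3 × 3 × 1 labels can merge adjacent parallel fibers in dense
  regions — inherent to uniform-width label generation.
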