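# Methods

This note documents the models, algorithms and numerical choices behind
`pnnmesh`, and what the synthetic phantoms do and do not establish about
behaviour on real confocal data.

## The problem

A perineuronal net (PNN) tiles the surface of certain neurons with
polygonal extracellular-matrix borders, each surrounding a single synaptic
bouton ("mesh units").  High-resolution morphometry of these units —
their number, area, perimeter, solidity, circularity, and the spatial
distribution of the chondroitin-sulfate (WFA) signal along each contour —
requires tracing thousands of individual mesh contours.  `pnnmesh`
implements the two tracing routes used in this line of work (a radial
semi-automated tracer and a conditional-GAN image-to-image tracer),
the geometry/polarity metrics they feed, and a synthetic phantom
generator that provides exact ground truth in place of the original
(undeposited) annotated confocal dataset.

## Synthetic phantoms (`lattice`, `render`, `dataset`)

**Tessellation.**  Mesh lattices are Voronoi tessellations of a jittered
hexagonal point grid.  With zero jitter the cells are regular hexagons;
site displacement (``jitter``, plus an extra ``diameter_cv`` term, both
as fractions of the grid spacing = ``mean_mesh_diameter``) spreads the
vertex-count distribution over 4–7 with pentagons/hexagons dominant,
matching the shape-class distribution reported by manual tracing of real
PNNs.  Voronoi cells cannot overlap, so every polygon is exact,
simple ground truth; cell adjacency comes from the shared Voronoi ridges.
Near-degenerate cell edges (< 1 px) are collapsed.  Defaults: 26 px mean
diameter, jitter 0.35, cv 0.15 — at the ~0.05 µm/px sampling typical of
high-NA confocal imaging this corresponds to ~1.3 µm mesh units.  An
optional annulus restricts meshes to a band, emulating the PNN coat in a
section through a soma.

**Rendering.**  The border signal is a ridge with Gaussian cross-section
(sigma 1.3 px) centred on the rasterised lattice edges, computed from a
Euclidean distance transform.  Three appearance regimes mimic the
qualitative classes seen in real data: *high-contrast* (sharp, low
noise), *blurred* (PSF sigma 2.4 px, lower peak level, stronger noise)
and *polar* (additive Gaussian blobs at the lattice vertices).  In the
polar regime the blob amplitude is analytically pre-compensated for the
PSF so that the post-blur vertex-to-edge peak ratio equals
``vertex_boost`` (an isotropic blur of sigma p scales a ridge peak by
`s_r/sqrt(s_r^2+p^2)` and an isotropic blob peak by `s_v^2/(s_v^2+p^2)`);
this closes the loop with the polarity index: a noise-free polar
rendering scores an index within 10% of ``vertex_boost``.  Detection is
modelled as PSF blur, then Poisson shot noise at a configurable photon
scale, then additive Gaussian read noise, then quantisation to 8 or
16 bits.  Three-plane stacks (Z−1, Z0, Z+1) scale the flanking planes'
structure by ``zplane_falloff``.

**Targets and patches.**  The training target for one mesh is the
rasterised contour of that mesh dilated to a half-width of 1 px (a ~3 px
line): single-pixel targets are needlessly hard for an image-to-image
model, and the dilation is reversible by skeletonisation.  Patches are
cut so the mesh centroid sits at the patch centre; meshes whose patch
crosses the scene border are skipped and counted.  The 80/20 random
train/test split is at the mesh level.

**What the phantoms do not model.**  No confocal optical-transfer
function (the PSF is an isotropic Gaussian), no multi-channel staining,
no tissue-scale context, no annotation errors in the ground truth, and
mesh-interior autofluorescence is a flat background.  Passing tests
therefore establish correctness of the algorithms and internal
consistency of the pipeline — not performance parity on real stained
tissue.

## Geometry and polarity metrics (`geometry`, `polarity`)

Contours are closed ordered-vertex polygons (pixel-centred coordinates,
x right, y down, canonical counter-clockwise).  Area is the shoelace
formula scaled by `pixel_size²`; perimeter the closed polyline length;
circularity `4πA/P²`; solidity `A / A_hull`.  The latter two are the
standard bounded shape descriptors; the source literature names the
metrics without formulas, so these definitions are package choices.
Contour simplification is Douglas–Peucker (shapely) followed by a
ring-aware cleanup that removes residual vertices lying within tolerance
of their neighbours' chord (DP alone may retain redundant ring vertices
at its split point); default tolerance is 5% of the equivalent diameter.
Shape classes are assigned from the simplified vertex count (3 →
triangle … ≥ 7 → polygon_7plus).

The **polarity index** is the mean intensity at the (simplified) contour
vertices divided by the mean intensity at the edge midpoints; intensities
are bilinear reads averaged over a 3×3 px neighbourhood for robustness
to ~1 px annotation jitter.  A mesh is *polar* when its index is strictly
above 1.5 — the published cut-off, with strict inequality following the
"above 1.5" wording.  The ratio form of the index is a documented
assumption (the original work displays vertex and edge-midpoint readouts
and the cut-off, not a formula); it is scale-invariant by construction.
Polar/nonpolar clusters are connected components of the mesh adjacency
graph restricted to same-label edges (union–find).

## Radial semi-automated tracer (`tracer`)

From a user-supplied centre (never auto-detected), 36 equiangular rays
(10° spacing; the number of directions is a package default, 8 minimum)
sample bilinear intensity at 0.5 px steps over [r_min, r_max], smoothed
with a 1 px Gaussian.  In 3-plane mode each ray reads all planes and the
plane with the highest maximum wins.  The contour point is placed at the
first local maximum whose height reaches 60% of the ray's global maximum
(``peak_rel_height``) — the nearest-to-centre preference made explicit.
A raw global argmax occasionally locks onto a brighter border junction
of a neighbouring mesh ~2× farther out; preferring the first prominent
peak removes those outliers while reducing to the global maximum on
clean unimodal profiles.  The hole-edge point is the first sample
strictly above the hole threshold walking outward, bounded by the contour
radius; the threshold defaults to 50% of the per-ray maximum (relative
mode, exposure-invariant; absolute mode available).  Rays with no sample
above threshold are flagged and filled by periodic interpolation from
their neighbours; more than 25% failed rays aborts the mesh as
unresolvable.  The contour connects the per-ray points directly (no
inter-ray interpolation).  Batch tracing estimates adjacency from traced
contours approaching within 2 px.

Measured on the phantom defaults (100 seeded meshes, 30 px diameter):
median absolute area error ≈ 1% both noise-free and at default noise,
against regression bounds of 5% / 12%.

## Conditional-GAN tracer (`pix2pix`, `nn`)

**Task.**  Image-to-image translation from a 128 px fluorescence patch
centred on one mesh to that mesh's contour-mask image; inputs and targets
are scaled to [−1, 1].

**Architecture.**  The generator is a U-Net: ``depth`` = 5 stride-2 4×4
convolution levels (LeakyReLU 0.2, instance normalisation except on the
first level), mirrored by stride-2 4×4 transposed convolutions (ReLU)
with skip concatenation at every resolution and a tanh output.  Channels
double from ``base_channels`` = 32 up to ``channel_cap`` = 64.  The cap
keeps the deepest layers from growing to 512 channels so that the
default CPU training run stays in the minutes range; it is a config
knob.  The discriminator is a PatchGAN: 3 stride-2 4×4 convolutions with
doubling channels, then a stride-1 1-channel logit map — a grid of
judgements over receptive-field-sized fragments (46 px with the
defaults; the analytic fragment diameter is exposed and unit-tested
against the gradient support of the convolution stack).  Judging local
fragments makes the discriminator a texture critic that assumes pixels
farther apart than one fragment are independent.

**Objective and training.**  Non-saturating BCE-with-logits adversarial
loss plus L1 reconstruction weighted by ``lambda_l1`` = 100; Adam with
learning rate 2e-4 and beta1 = 0.5 (the canonical recipe for this model
family).  Batch size 4–8 (default 8) for CPU matmul throughput.  Per
batch, one generator forward is shared: the discriminator sees the
(input, target) and (input, fake) pairs, and both networks' gradients
are computed before a simultaneous Adam step for each — saving a second
generator forward relative to strictly alternating updates.  Instance
normalisation replaces batch normalisation (batch-size independent,
deterministic at inference) and decoder dropout is omitted
(determinism).  Training is fully seeded: parameter init, data order and
noise all derive from one integer; a non-finite loss raises with the
last completed epoch's parameters preserved.  Snapshots of generator
outputs on a probe set fixed before training can be recorded at chosen
epochs to visualise learning progress.

**Backend.**  No deep-learning framework is used: convolutions are
lowered to BLAS matrix multiplication via an im2col/col2im pair in a
layout whose reshapes are views, transposed convolutions reuse the same
kernels through the conv/conv-transpose duality, and every layer carries
a hand-written backward pass (verified against central finite differences
in float64).  Single-threaded, float32.

**Mask → contour.**  Binarize (0.5) → morphological closing (disk 2,
bridges small gaps) → skeletonize (recovers the centre-line, undoing the
target dilation) → 4-connected flood fill of the interior from the patch
centre (fill escaping to the border means no closed loop: extraction
fails, flagged not fatal) → subpixel boundary via marching squares.
The marching-squares boundary of interior∪skeleton sits about half a
pixel outside the centre-line with an orientation-dependent offset;
shrinking it to the mid-area between that boundary and the
interior-only boundary cancels the offset (a 20 px-radius circle mask
recovers its area to 0.1%).  The polygon is then Douglas–Peucker
simplified (0.8 px).  In the evaluation pipeline, extraction backs off
through binarization thresholds 0.5 → 0.35 → 0.25 and then through a
larger closing radius (4 px, bridging wider ring breaks) before
declaring failure: a mildly under-saturated or locally interrupted
predicted ridge is still a valid trace, and the escalation steps only
affect masks that would otherwise fail.

**Evaluation.**  For every test mesh both the predicted mask and the
ground-truth target mask are pushed through the identical extraction and
geometry pipeline (symmetric treatment: reference annotations in real
data are themselves traced contours), yielding a per-mesh area/perimeter
table, Pearson and Spearman area correlations (scipy implementations;
the test suite cross-checks them against hand-written textbook
formulas), per-provenance means, and a failed-extraction count.  The
exact generating-polygon area is carried as an extra column for
synthetic data.

**Problem sizes.**  The default training exercise used throughout the
package is 200 pairs of 128 px patches for 30 epochs on one CPU
(roughly 10–15 minutes), evaluated on 50 held-out meshes; the
reproducibility check runs a 2-epoch pipeline twice.  These sizes are
package choices for a desk-scale, deterministic exercise of the full
method; the original model was trained on thousands of annotated meshes
for over a hundred epochs.

## Reproducibility

Every stochastic step takes an explicit integer seed; derived seeds stay
below 2³¹.  `simulate → split → train → evaluate` under one seed yields
bit-identical loss histories and report tables across runs on the same
platform (exercised in the acceptance suite).  CLI commands write a run
manifest with the resolved configuration, seed, package versions and
input hashes.

## Known limitations

- The phantom's appearance model is deliberately simple (Gaussian ridge
  + Gaussian PSF); no claim is made about performance on real WFA
  stains.
- The polarity-index formula and the mask→contour procedure are package
  constructions where the source work is silent; both are documented
  above and parameterised.
- The classical tracer assumes a star-shaped mesh about the chosen
  centre (radial parameterisation); strongly non-convex meshes would
  need a different contour model.
- Whether the 1.5 polarity cut-off applies to 2-D, 3-D or both analyses
  is not specified in the source; the package treats it as
  dimension-agnostic.
- Single-channel only; multi-channel (e.g. synapse marker) analysis is
  out of scope.
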