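# pnnmesh

Tracing and quantifying single perineuronal-net (PNN) mesh units in
high-resolution fluorescence microscopy.

PNNs are lattice-like extracellular-matrix coats on certain neurons; each
polygonal *mesh unit* of the lattice surrounds one synaptic bouton.
Morphometry of these units — area, perimeter, solidity, circularity
(`4πA/P²`), vertex-count shape class, and the polarity of the
chondroitin-sulfate signal along the contour — requires tracing thousands
of individual mesh contours in WFA-stained confocal images.  `pnnmesh`
provides the full toolchain:

- **`pnnmesh.lattice` / `render` / `dataset`** — a synthetic phantom
  generator: Voronoi mesh lattices with exact polygonal ground truth,
  rendered as ridge-like border fluorescence in three appearance regimes
  (high-contrast, blurred, vertex-enriched "polar"), with PSF blur,
  Poisson/Gaussian noise, optional 3-plane z-stacks, and paired
  (image patch, contour mask) training corpora with an 80/20 split.
- **`pnnmesh.tracer`** — the radial semi-automated tracer: from a
  user-selected mesh centre, equiangular rays locate the border as the
  first prominent radial intensity maximum (across one or three
  z-planes) and the mesh hole as the first sample above threshold.
- **`pnnmesh.pix2pix` / `nn`** — a conditional-GAN image-to-image tracer
  (Model 1): a U-Net generator translates a single-mesh patch into its
  contour-mask image, trained adversarially against a PatchGAN fragment
  discriminator with an L1 reconstruction term
  (`L = L_adv + λ·L1`, λ = 100, Adam lr 2e-4, β₁ 0.5).  The networks are
  implemented directly in NumPy with hand-written backpropagation over
  im2col convolutions — no deep-learning framework — and train on one
  CPU in minutes at the package's default problem sizes.
- **`pnnmesh.geometry` / `polarity` / `extract` / `evaluate`** — shape
  descriptors, the polarity index (mean vertex intensity / mean
  edge-midpoint intensity, polar iff > 1.5), polar-cluster detection,
  mask→polygon extraction, and the predicted-vs-truth evaluation report
  (per-mesh table, Pearson/Spearman area correlations, means, failures).
- **`pnnmesh.cli`** — `pnnmesh simulate | trace-classical | train |
  predict | evaluate | geometry`, driven by one YAML config and one seed,
  writing a run manifest per command.

## Worked example

```python
import pnnmesh as p

# 1. phantom corpus with exact ground truth, 80/20 split
lat  = p.LatticeParams(n_meshes=170, mean_mesh_diameter=26, domain_size=(640, 640))
rend = p.RenderParams.for_regime("high_contrast")
ds   = p.make_patch_dataset(2, lat, rend, patch_size=128, seed=0)
train_set, test_set = p.split_dataset(ds, 0.8, seed=0)
train_set, test_set = train_set.take(200), test_set.take(50)

# 2. fit the conditional-GAN tracer
tracer  = p.Pix2PixTracer(train_set, eval_set=test_set)
results = tracer.fit(p.TrainConfig(epochs=30, seed=0))
print(results.summary())

# 3. evaluate traced geometry against ground truth
report = results.evaluate(test_set)
print(report.summary())
```

Output of the two summaries (30 epochs, seed 0, one CPU):

```
Pix2Pix mesh tracer (Model 1)
==============================================
generator      U-Net depth 5, base 32, cap 64
discriminator  PatchGAN, fragment diameter 46 px
patch size     128 px, epochs trained 30
final losses   G_adv 2.1095  G_L1 0.0140  D 0.3233
test L1        epoch 1: 0.6632 -> final: 0.0168

Mesh-geometry evaluation: model vs ground truth
================================================
meshes evaluated        42
failed extractions      8
area Pearson r          0.9916
area Spearman rho       0.9843
mean area (px^2)        truth 564.9  model 554.1
mean perimeter (px)     truth 90.4  model 88.4
```

The generator's L1 distance to the target masks falls ~40-fold over
training, and the areas of the contours extracted from the predicted
masks correlate with the ground-truth areas at r ≈ 0.99 — the learned
tracer reproduces single-mesh geometry on held-out meshes (the few
failed extractions are predictions whose contour ring still has a break
wider than the morphological bridging; they are counted, not silently
dropped).  The classical tracer closes the same loop from the other
side:

```python
contour, hole, rays = p.trace_mesh_radial(scene_image, center=(96.0, 88.0))
geom = p.compute_geometry(contour)         # area, perimeter, circularity, solidity
prof = p.polarity_index(scene_image, p.simplify_contour(contour))
```

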