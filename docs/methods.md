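# Methods

This note documents the models, conventions and design choices behind
`nervemetrics`, in the order data flows through the pipeline.

## Coordinate and raster conventions

Rasters are indexed `(row, col)`, 0-based, pixel centers at integer
coordinates; windows are half-open pixel ranges.  Physical resolution is
carried as µm/px (default 0.125 µm/px, i.e. 8 px/µm light microscopy)
and physical units are authoritative in all user-facing tables: window
sizes are specified in µm and converted by `round(side_um/resolution)`.
Semantic class codes: background 0, axon 1, myelin 2.

## Phantom generator

The generator emulates the *statistical structure* of semantic
segmentations of toluidine-blue-stained nerve cross-sections, not their
appearance.  Myelinated fibers are concentric disks (axon radius `r_a`,
fiber radius `r_f = r_a/g`) placed by random sequential adsorption (dart
throwing) inside elliptical fascicles until a target tissue packing is
reached or an attempt budget is exhausted (a partial render reports its
achieved packing; it is not an error).  A pixel belongs to a shape iff
its center lies strictly inside it — this makes exact pixel-count
oracles possible and guarantees tangent fibers share no pixel.

Defaults (chosen as generic mammalian-nerve-plausible values):

| parameter | default | note |
|---|---|---|
| fiber diameter | log-normal, median 6 µm, log-sd 0.35 | positive, right-skewed; optional two-component mixture for bimodal spectra |
| g-ratio | truncated normal, mean 0.60, sd 0.06 on (0.30, 0.90) | support strictly inside (0, 1) |
| target packing | 0.55 | axon+myelin fraction of fascicle area |
| minimum boundary gap | 0 px | touching myelin is the default so the watershed split is actually exercised |
| resolution | 0.125 µm/px | |

Group effects: implanted samples (sham, stim) retain a fraction
(default 0.85) of placed fibers — thinning a random subset of exactly
`round(p·n)` fibers so the retained count is monotone in the
multiplier — and have their myelin thickness multiplied (default 0.90).
Stimulated samples additionally scale both effects as
`exp(−slope·(k − k_sham))` with Shannon *k*, slopes 0.06 (density) and
0.04 (myelin), sham baseline k = −4 (negligible 2 µA stimulation).
Setting all multipliers to 1 and slopes to 0 yields a null study whose
groups are exchangeable.  Studies derive per-sample seeds from the
master seed via `numpy.random.SeedSequence.spawn`, and add mild
between-sample jitter (packing sd 0.015, log-caliber sd 0.03) as
biological variability.

What the phantom does **not** emulate: staining texture and noise (the
input boundary here is a semantic map, not an image), unmyelinated or
degenerated/hypomyelinated fibers, vasculature, non-elliptical fascicle
geometry, and spatially correlated fiber loss (lesions are uniform
thinning, not focal).  Consequently, passing tests demonstrate the
*measurement* chain is correct and the *analysis* recovers planted
effects; they do not certify segmentation quality on real histology.
Note also that dart throwing cannot place fiber centers within one
fiber radius of the fascicle boundary, so phantoms have a thin
low-density rim; interior-vs-global density comparisons in tests use
fibers small relative to the fascicle for this reason.

## Instance segmentation

Cleanup rules, applied once, in order, each deletion setting pixels to
background:

(a) myelin outside the include mask is cleared, and any axon component
with a pixel outside the mask is deleted (partial fibers at mask borders
are unmeasurable — this is the stricter of the possible readings and is
flagged in the output sidecar);
(b) axon components under `min_axon_px` (default 4 px) are deleted;
(c) axon components 4-adjacent to background are deleted (degenerated /
hypomyelinated morphology is out of scope);
(d) myelin components not 4-adjacent to a surviving axon are deleted.

Connectivity: 8-connectivity for component labeling (diagonal
anti-aliasing artifacts stay one component), 4-adjacency for the
adjacency tests (stricter; avoids diagonal leaks).  The operation is
idempotent.  When two fibers share one myelin component and only one
axon is deleted, the shared myelin survives through rule (d) — a known
limitation of component-level cleanup.

The height map uses the exact Euclidean distance transform; myelin
height is `d_axon/(d_axon + d_background)`, axon 0, background 1.  With
no background pixels in the map the background distance is +∞ and myelin
heights take the limiting value 0.  The watershed (scikit-image) floods
tissue pixels (4-connected) from the axon seeds in ascending height,
breaking ties by queue insertion order, so outputs are bit-reproducible;
it is validated in the tests against an independent Dijkstra
minimax-path oracle on the pixel graph.

## Morphometry

Areas are pixel counts × resolution².  The perimeter for circularity is
the marching-squares boundary polygon smoothed by a circular moving
average (window 5): raw marching-squares zigzag inflates perimeters by
~5%, biasing disk circularity to ~0.90, while the smoothed polygon keeps
disks within ~1% of circularity 1.  A discretization allowance of ±0.1
on circularity applies at radii ≥ 10 px.  Aspect ratio is
major/minor axis of the second-moment ellipse (ellipse fit, not bounding
box); a degenerate 1-px-wide region reports NaN and its row is excluded
from regression datasets (the exclusion is counted).  "Mean diameter" is
the mean caliper (Feret) diameter over 32 uniformly spaced orientations
measured on the convex hull of the pixel squares; it is an auxiliary
output, not one of the 7 analysis features.  The g-ratio is computed
once as `√(A_axon/A_fiber)`, which is algebraically identical to the
equivalent-diameter ratio.

## Window metrics

The window anchor sits at offset `(side−1)//2` from the window's
top-left; for even pixel sides this is the top-left pixel of the central
2×2 block.  Windows are clipped at image borders and the fascicle-area
denominator shrinks accordingly (no content padding).  Fiber membership
for fractional counting is axon ∪ myelin pixels.  Densities are reported
per mm² of fascicle area.

The pixel-wise engine computes all pixel counts from exact int64
integral images and accumulates fractional fiber contributions fiber by
fiber in ascending id order; because the single-window routine performs
the identical float operations in the identical order, engine output is
bit-identical to the naive per-pixel loop and independent of the
processing chunk size.  Exact conservation (partition sums equal the
fiber count) holds up to one float rounding per fiber fraction
(~10⁻¹⁵ relative); tests assert 10⁻⁹ relative.

## Regression

Hyper-parameters: RBF γ = 1/n_features, 100 Nystroem components
(landmarks subsampled from the training rows), SGD with squared loss,
L2 penalty α = 10⁻⁴, intercept, max 200 000 iterations, tolerance
10⁻¹², shuffling, inverse-scaling learning rate.  `C`, `ε` and the
kernel tolerance are carried in the spec for completeness of the SVR
parameterization but are inert under the squared-loss SGD formulation.
Three quantities the upstream parameterization leaves open are fixed
here and recorded in fitted-model metadata: features are z-score
standardized before the kernel (required for a shared γ across
mixed-unit features; parameters fit on training rows only), the learning
rate constants are (η₀, power) = (0.01, 0.25), and the 70/30 split is
over measurement rows (a sample-level split is available as an option
for leakage-averse use, since row splits let rows of one nerve appear on
both sides).  Sham rows legitimately appear in both regressions'
training data.  R² is implemented definitionally (1 − SS_res/SS_tot) on
the held-out 30%; a constant predictor at the validation mean scores
exactly 0.

## Density summaries

FFT KDE: Gaussian product kernel; per-dimension bandwidth
`h_i = σ_i·n^(−1/6)` (Scott's rule for d = 2 with the sample SD);
linear (bilinear) binning on a 256² grid padded by 4 bandwidths per
side; FFT convolution; then renormalization of the grid mass to 1
(4-bandwidth truncation leaves ~6·10⁻⁵ outside the grid, so
renormalization happens after padding).  "1 σ"/"2 σ" regions are
highest-density regions at 68%/95% mass — density superlevel sets found
by sort-and-accumulate — not per-axis sigma ellipses; multimodal clouds
may produce several disjoint contour loops, all drawn.

## Pipeline and problem sizes

The pipeline writes every stage's outputs plus a deterministic manifest
(config, seeds, versions, decision values); wall-clock timings go to a
separate file so re-runs are bit-for-bit comparable.  Default study
design mirrors a three-group implantation study: 8 control, 5 sham, 6
stimulated samples with Shannon-k levels spanning roughly −3.5 to 2
(one level above the k = 2 safety boundary).  Tests and the acceptance
script run phantoms of 160–600 px and windows of 8–25 µm — fields large
enough for tens to hundreds of fibers per sample while keeping the full
suite under two minutes; the measurement code is size-agnostic and the
default window sizes remain 200 µm and 37.5 µm.

## Known limitations

* Cleanup is component-level; shared myelin of a deleted fiber can
  survive attached to a neighbor.
* The quadrat comparison mode reproduces the legacy window-area
  denominator and therefore inherits its downward bias near fascicle
  borders — by design.
* Phantom effects are global per sample; the analysis's ability to
  localize focal damage is not exercised by the synthetic studies.
* The regressions inherit SGD's sensitivity to extreme feature scales;
  standardization mitigates but does not remove it for heavy-tailed
  features.
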