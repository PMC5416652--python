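# Methods

## The model

`tonguelab` implements a cascade classifier for tongue-body colour with
three classes: light red, red, deep red. The cascade's premise is that
the three-way problem splits into an easy binary margin problem and a
narrow colour-threshold problem:

* **Deep red vs the rest** is separable by overall chromatic intensity:
  deep-red tissue is darker and less chromatic, so its colour clusters
  sit nearer Lab black (0, 0, 0). A soft-margin SVM on cluster-level
  colour features handles this.
* **Red vs light red** differ mainly in luminance (their chromatic
  ranges nearly overlap), which an explicit L*-anchored rule captures
  better than a learned boundary — and keeps the decision auditable by
  practitioners.

All geometry is Euclidean in CIELAB. No perceptual distance (CIEDE2000
etc.) is used anywhere; the thresholds and the clustering metric are
defined on raw (L*, a*, b*) coordinates.

### Colour conversion

Inputs are 24-bit sRGB images in which exact black (0, 0, 0) is a
reserved background sentinel (segmentation and coating removal are
upstream, out of scope). Conversion to CIELAB assumes sRGB companding,
D65 reference white, 2° observer — the sRGB defaults; the acquisition
systems this targets produce colour-corrected sRGB, but the white point
is an assumption, so it is pinned in one module (`colorspace`) rather
than spread through the code. Exact-black pixels are forced to Lab
(0, 0, 0) and excluded from the foreground mask instead of being run
through the converter, making "distance from the black pixel" exact in
both spaces.

### Clustering and identifiers

k-means runs on all pixels (background included) with k = 4:
background, deep-red region, red/light-red region, transitional region.
Parameters: k-means++ seeding, `n_init = 5` restarts keeping the
lowest-inertia solution, `max_iter = 300`, `tol = 1e-4` (relative
change in inertia, the scikit-learn convention), deterministic per
seed. A config switch (`cluster_background = False`) clusters
foreground pixels only into k − 1 clusters and appends a synthetic
black background cluster; the default clusters everything and detects
the background cluster afterwards as the centroid nearest black (ties
to the lowest id).

Two identifier rules pick the informative clusters:

* **Max colour distance**: argmax over non-background clusters of the
  centroid's Euclidean distance from black. The centroid (not the
  member mean) is used in the ranking; at convergence they coincide to
  solver tolerance, but the contract pins the centroid because the
  identifier is defined on the clustering solution itself.
* **Max coverage area**: argmax of the tight bounding-box area
  w′ × h′ of member pixels (inclusive pixel extents). The box reading
  is the default because the quantity is defined through w′ ≤ w,
  h′ ≤ h; a pixel-count alternative (`metric = "count"`) is available
  since "number of nonzero pixels" is the other natural reading.
* **Collision rule**: if one cluster wins both, the coverage identifier
  is demoted to its runner-up (the distance identifier is an explicit
  formula on a fixed reference point; the coverage identifier is the
  more heuristic of the two) and the selection is flagged.

Features are, by default, the concatenated mean Lab colours of the two
identifier clusters (6-dim, one instance per image), because stage-1
prediction is per image. An "instance" mode emits the two 3-dim
summaries as separate training rows (2N instances from N images,
matching the original accounting of 600 instances from 300 images);
image-level prediction in that mode aggregates the two votes by
majority with deep-red priority on a split — that aggregation has no
canonical definition, so it is documented here as this package's
choice.

### Stage 1: SVM

scikit-learn's SVC behind a stable surface. Kernels: linear (default),
RBF, polynomial (degree 3), quadratic (degree 2); the polynomial
kernels use the inhomogeneous form (u·v + 1)^d — the homogeneous
degree-2 form is blind to sign and cannot separate opposite clouds.
C defaults to 1.0 (no regularisation value is canonical for this
problem; exposed in config). Features are z-scored with statistics
learned on the training split only and frozen in the model (L* spans
0–100 while b* spans a few units; unscaled fits would let L* dominate
the margin). `standardize=False` gives the raw max-margin problem,
used by tests that compare against a directly solved QP. The
support-vector count (points with nonzero dual coefficient) is recorded
on every model: prediction cost is linear in it, and the identifier
features exist to shrink it.

### Stage 2: colour ranges

Red box: L* < 56, 32 ≤ a* ≤ 39, 6 ≤ b* ≤ 10. Light-red box: L* ≥ 56,
23 ≤ a* ≤ 27, 15 ≤ b* ≤ 19. All chromatic bounds inclusive; L* = 56
belongs to light red. The two boxes are disjoint in L*, so the check
order (red first) cannot change an in-box result. Points outside both
boxes — the chromatic gaps, e.g. 27 < a* < 32 — fall back to luminance:
L* below the threshold is red, otherwise light red. The fallback
threshold defaults to 56 because that is the only luminance boundary
the ranges define; it is configurable separately from the box split.
The classified colour is the mean Lab colour of the max-distance
(red/light-red) identifier cluster, not the whole-tongue mean
(configurable to the whole-foreground mean). The rule is total: every
finite Lab point receives exactly one label.

A `chromatic_only_classify` variant ignores L* entirely and abstains
outside (or, for user-edited overlapping boxes, inside both) chromatic
boxes; it exists for the ablation comparing chromatic-only against
full-Lab ranges, not for production use.

Rule sets round-trip through YAML so practitioners can substitute
ranges derived from their own corpora; `range_statistics` reports
per-class min/percentile/max of cluster means to support that, but
automated range fitting is deliberately out of scope.

### Evaluation harness

`evaluate_corpus` uses stratified 5-fold cross-validation with a fixed
seed (no canonical split protocol exists for this design; the protocol
string is embedded in every report). Clustering features are
label-independent and deterministic per image, so they are computed
once and shared across folds; only the SVM is refitted. Reported:
3-class accuracy, stage-1 binary accuracy, stage-2 accuracy conditional
on stage 1 forwarding the image, per-fold support-vector counts, and
wall time per image. Runtime is informational only — never an
acceptance gate, since it is hardware-dependent. The decomposition
"overall correct = correct deep reds + (stage-1-correct ∧
stage-2-correct) red/light-reds" holds exactly and is asserted in
tests.

`compare_kernels` reproduces the kernel × feature-set comparison
design. The raw-pixel baseline draws a fixed budget (default 500) of
foreground Lab pixels per image uniformly at random (deterministic per
image seed) and flattens them — a desk-scale stand-in for training on
raw images.

## Synthetic data

The generator emulates post-segmentation tongue images: an ellipse
(semi-axes 0.30–0.38 of width, 0.38–0.46 of height, small centre
jitter) on exact-black background, with four regions that give k = 4
clustering genuine structure:

* **body** — class-conditional mean colour: light red (62, 25, 17) and
  red (50, 35, 8) sit inside their respective rule boxes; deep red
  (35, 20, 2) is darker and less chromatic than both, i.e. nearer
  black, which is the property stage 1 exploits.
* **accent** (tip + bilateral edges) — body colour shifted +4 in a*,
  the more chromatic band clinicians inspect first.
* **transitional rim** — body colour scaled by 0.6 towards black, the
  boundary band left by segmentation.
* **background** — exact (0, 0, 0); any foreground pixel that would
  quantise to exact black is nudged to (1, 1, 1) to keep the sentinel
  unambiguous.

Noise is i.i.d. Gaussian per channel in Lab (default sd 2.0), added
before 8-bit sRGB quantisation; adding it in Lab keeps effect sizes
interpretable against the rule-box widths (4–7 Lab units), and
quantisation contributes at most ~1 RGB unit of extra rounding. Class
counts follow the mixture by largest-remainder apportionment; per-image
seeds derive from the corpus seed, so corpora are byte-reproducible.

What the generator does **not** emulate: papillae and coating texture,
specular highlights, illumination gradients, camera noise correlation,
or the narrow, overlapping colour gamut of real tongues. Passing tests
therefore demonstrate that the pipeline recovers class structure of the
kind the method assumes — not clinical performance. In particular the
synthetic classes are better separated than clinical ones, so measured
accuracies on synthetic corpora sit near the ceiling; direction-style
properties (e.g. identifier features needing fewer support vectors than
raw pixels) transfer more credibly than magnitudes.

One interaction is worth noting: with the +4 a* accent shift, the
max-distance cluster of a light-red image averages a* ≈ 29, outside the
light-red chromatic box (23–27). Those images are classified through
the luminance fallback — correctly, since their L* ≥ 56 — which is
exactly the role the fallback plays on real images whose chromatic
values stray from the boxes. The body-region colours themselves land in
the correct box on ≥ 95% of images, which tests assert.

## Numerical choices and degenerate inputs

* Ties in every argmax/argmin (background detection, both identifiers,
  equidistant pixels in assignment) break to the lowest cluster id.
* k-means requires at least as many distinct pixel values as clusters;
  fewer raises a degenerate-input error rather than returning empty
  clusters. k < 2 (clustering) and k < 3 (pipeline, which needs a
  background plus two identifier candidates) are parameter errors.
* Identifier selection requires ≥ 2 non-background clusters; empty
  clusters are skipped in coverage ranking; an empty cluster passed to
  `coverage_area` raises.
* Single-class training sets and non-finite features are rejected
  before fitting; prediction validates feature dimensionality.
* Accuracy on an empty evaluation set raises (no 0/0).
* `lab_to_rgb` clips out-of-gamut values; the round trip through 8-bit
  RGB is within ±1 channel unit for in-gamut colours.

## Problem sizes

Default test and acceptance workloads: the study corpus is 300 images
at 256 × 256 (the corpus size the method was designed around); module
tests use 96 × 96 images, which preserve the four-region structure at a
fraction of the clustering cost; the support-vector comparison uses ten
matched 60-image corpora at 96 × 96. These sizes are the package's
standard configuration for reproducible desk-scale runs.

## Known limitations

* The synthetic corpus is the only bundled data source; clinical
  validation requires a practitioner-labelled corpus and likely
  re-derived colour ranges (`range_statistics` helps).
* The colour-range thresholds are corpus-derived constants, not fitted
  parameters; on differently calibrated hardware they should be
  re-derived rather than trusted.
* Stage-1 errors are unrecoverable downstream: a deep-red verdict
  short-circuits the cascade by design.
* The luminance fallback guarantees totality but compresses all
  out-of-box colours onto a single L* threshold; genuinely anomalous
  colours (e.g. blue-ish tongues) are still labelled red or light red
  rather than flagged.
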