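# Methods

## Pipeline overview

`nucseg` composes four stages around a pluggable instance segmenter:
stain color normalization onto a template image, overlapping-tile
inference for images larger than the tile size, multiple-inference
(test-time-augmentation) fusion of per-variant predictions, and
object/pixel-level evaluation. Each stage is usable on its own; the
`segment_image` entry point wires them according to a `PipelineConfig`.

## Stain color model and transfer

Pixel colors of an H&E image are modeled as a K-component multivariate
Gaussian mixture, K = 3 by default for the three tissue classes a
pathology slide presents: hematoxylin-stained nuclei, eosin-stained
surrounding tissue, and unstained background.

**Working color space.** The default codec maps intensities to optical
density, `OD_c = −log((I_c + 1)/256)` per channel. Stain absorption is
approximately linear in OD (Beer–Lambert), which makes the per-class color
clusters closer to Gaussian than in raw RGB; plain RGB is available via
`colorspace: rgb`. The codec round-trips within one intensity level.

**Fitting.** Classical EM on the pixel cloud. Initialization is
deterministic: component means start at the mean color of narrow bands
around the K evenly spaced quantiles of the luminance ordering, weights
start uniform, covariances at the global color covariance; the seed only
adds a vanishing (1e-9) jitter to break exact ties. Covariances are
floored by `ε·I` with `ε = 1e-6 ×` the mean per-channel variance, which
prevents singular whitening on flat background regions. Iteration stops
when the relative log-likelihood improvement falls below `em_tol`
(default 1e-6) or after `em_max_iter` (default 500) iterations;
non-convergence returns the last state with a logged warning. The returned
posterior is the E-step that fed the final M-step, so one further M-step
(`estimate_class_gaussians`) reproduces the returned parameters exactly —
this makes the EM fitter interchangeable with any external posterior
provider (e.g. a learned tissue-segmentation network) behind the same
interface.

**Transfer.** With component correspondence established by
`align_components` (exhaustive minimum-total-mean-distance matching over
K! permutations, refused for K > 8), each pixel with color x and
responsibilities γₖ maps to

    x' = Σₖ γₖ [ Sₖ (x − μₖ_in) + μₖ_tmpl ],   Sₖ = (Σₖ_tmpl)^{1/2} (Σₖ_in)^{−1/2}

with symmetric matrix square roots via eigendecomposition
(basis-independent, no Cholesky ordering artifacts). The result maps back
through the codec and clips to [0, 255]. When input and template models
coincide the map is the identity up to quantization. Only the input's
posterior weights the transfer; the template contributes its class
Gaussians alone.

## Tiling and stitching

Per axis of extent D with tile size t, crop offsets are
`{0, (D−t)//2, D−t}` (deduplicated, sorted); tiles are the Cartesian
product. For D = 1000, t = 500 this yields the nine overlapping 500×500
windows at offsets {0, 250, 500}²; a tile equal to the image gives the
single full-image window. Windows are half-open `[r0, r0+t) × [c0, c0+t)`
with 0-based (row, col) coordinates.

Stitching places each tile instance at absolute coordinates and merges
duplicate detections of the same nucleus: two instances from different
tiles merge (pixel union) when their IoU ≥ `merge_iou` (default 0.5) **or**
their intersection over the smaller instance ≥ `containment` (default
0.8) — the containment rule absorbs a seam-cut fragment into the whole
nucleus seen by the overlapping tile. Merging is transitive via
union-find, so a nucleus seen in three or more tiles collapses to one
instance regardless of pair order. Remaining pixel conflicts between
unmerged instances go to the instance whose centroid lies farther from
its source-tile boundary, on the grounds that the tile that saw the
nucleus more centrally segmented it more completely. The stitcher is
invariant to tile ordering, and stitching the crops of a ground-truth
mask reproduces it exactly whenever every instance is wholly contained in
at least one tile.

## Augmentation group and TTA fusion

The inference-time transform set is identity, counter-clockwise rotations
of 90/180/270°, and horizontal, vertical, and combined flips — seven
variants with the original first. Every member has its exact inverse in
the set and preserves pixel values (no interpolation), so masks survive
apply-then-invert bit-for-bit. Note that flipping both axes equals the
180° rotation, so the list contains one duplicate pair (`rot180` ≡
`hvflip`) by construction; the fused vote simply counts that prediction
twice in both numerator and denominator, which leaves a deterministic
segmenter's majority unchanged. Rotation direction is fixed counter-
clockwise as a convention; only the inverse relation matters for
correctness.

Fusion inverts each per-variant prediction to the original frame, then for
each nucleus of the **original** prediction collects every instance of the
seven inverted masks with IoU strictly above `iou_threshold` (default
0.2) — the reference nucleus matches itself at IoU 1, and multiple
instances from the same variant may all enter the matched set. A pixel of
the fused nucleus is kept iff it appears in strictly more than
`vote_threshold` (default 0.5) × M of the M matched masks; the denominator
is the matched-set size rather than a fixed 7, so variants that missed the
nucleus entirely do not veto it. Nuclei detected only in augmented
variants are discarded (fusion never invents instances). Pixels claimed
by two fused nuclei go to the one with the higher vote fraction, ties to
the smaller original label.

## Baseline segmenter

The desk-scale backend is classical: the nuclei-class posterior of the
3-component stain GMM (the component with the highest mean optical
density, i.e. the darkest class) serves as the nuclei-likelihood map, with
inverted luminance as a fallback for degenerate inputs; Otsu's threshold
binarizes it; holes are filled; the Euclidean distance transform is peaked
at local maxima separated by at least the estimated nucleus radius
(median-component-area based, floor 3 px); marker-controlled watershed
splits touching nuclei; instances below `min_area` (default 30 px) are
discarded. Deterministic given the seed. Any other detector can be plugged
in through `SegmenterBackend`, whose wrapper enforces the label-mask
invariants on the output; `MaskRCNNConfig` records the adapter settings an
external Mask R-CNN would use, and `resolve_overlaps` flattens overlapping
scored soft masks into a label map (per-pixel highest score, ties to the
larger instance then smaller index).

## Metrics

Instances are matched one-to-one greedily by descending Dice coefficient
(ties: smaller ground-truth label, then smaller predicted label), a pair
counting as a true positive only when Dice strictly exceeds 0.2 ("0.2
exactly" does not match). Precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2TP/(2TP+FP+FN), with 0/0 defined as 0. ADC averages Dice over the
matched pairs only — the alternative readings (over all ground-truth or
all predicted instances) are not used, since ADC co-reports with
object-level F1. AJI iterates ground-truth nuclei in ascending label
order, takes each one's best-Jaccard prediction (ties to the smaller
predicted label), accumulates the pair's intersection and union, adds
unmatched ground-truth sizes and every never-used prediction's size to
the union, and returns the ratio. A prediction may be the best match of
several ground-truth nuclei; it is only excluded once from the unused
sum. Greedy one-to-one matching can in principle differ from the
cardinality-maximal matching; the brute-force oracles in the test suite
quantify this on random cases (no discrepancy observed at the tested
sizes).

## Synthetic generator

Each image is built from three planted color classes (defaults: nuclei
RGB (105, 65, 160), tissue (205, 140, 170), background (238, 235, 238),
per-channel std 8/8/4) on a 256×256 canvas with 20 nuclei — ellipses with
semi-major axis 6–12 px, eccentricity 0–0.6, random orientation —
placed by rejection sampling until pairwise disjoint (budget 100·n
attempts, then a hard error naming the achieved count). A smoothed-noise
threshold field defines the blobby tissue region. Stain variation is a
global additive shift of all class means, mimicking over-/under-staining;
`noise_std` (default 3) adds white noise on top of the per-class spread.
Colors are diagonal-covariance Gaussians per class — deliberately simpler
than the full-covariance fitter, which must recover the planted
(diagonal) truth. What the generator does **not** emulate: chromatin
texture, stain optics, out-of-focus blur, touching/overlapping nuclei
clusters, mitotic figures. Passing the desk-scale benchmark therefore
shows the pipeline's stages compose correctly and recover controlled
perturbations, not that the baseline segmenter would match a trained
detector on real tissue.

## Benchmark sizes and defaults

The end-to-end benchmark uses 10 synthetic 256×256 images in the easy
regime (20 disjoint nuclei, noise_std 1, global stain shift
(15, −10, 5)) with tile size 160, which exercises the same 3×3
overlapping-tile geometry as 500 px tiles on a 1000 px scan while keeping
the full normalize + tile + TTA + stitch path fast on one CPU. The
acceptance bar (mean object-level F1 ≥ 0.7, AJI ≥ 0.5) is this package's
own desk-scale criterion; observed values are near 1.0.

## Known limitations

* The stain model assumes three color classes; slides with strong
  additional chromogens (e.g. IHC counterstains) would need a larger K
  and a correspondingly different component-alignment heuristic.
* EM responsibilities use color only; a spatially aware posterior
  provider (a segmentation network) can be substituted but is not
  included.
* The stitch conflict rule (centroid-to-border distance) is a heuristic;
  soft-mask blending across tiles is out of scope.
* The greedy instance matcher is not guaranteed cardinality-maximal,
  though it agrees with brute force on all tested cases.
* The baseline watershed under-segments heavily overlapping nuclei; the
  synthetic benchmark keeps nuclei disjoint for that reason
  (`overlap_allowed` exists for stress tests, not for the benchmark).
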