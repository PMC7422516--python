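# nucseg

Nuclei instance segmentation toolkit for H&E-stained histopathology images.

Hematoxylin and eosin staining varies strongly between labs, scanners and
slides, and that color variation degrades any downstream nuclei detector.
`nucseg` implements the bespoke stages that wrap around a pluggable instance
segmenter:

* **Stain color normalization** — pixel colors are modeled as a 3-class
  Gaussian mixture (nuclei / surrounding tissue / background) fitted by EM
  in optical-density space. An input image is normalized onto a template by
  the responsibility-weighted per-class Gaussian transport
  `x' = Σₖ γₖ [ (Σₖᵗ)^{1/2} (Σₖⁱ)^{-1/2} (x − μₖⁱ) + μₖᵗ ]`.
* **Overlapping-tile inference** — a large image is cropped at per-axis
  offsets {0, (D−t)/2, D−t} (a 1000 px image with 500 px tiles yields the
  standard 9 overlapping windows) and per-tile predictions are stitched
  back with IoU/containment duplicate merging.
* **Multiple inference (TTA) fusion** — the segmenter runs on 7 geometric
  variants (identity, rotations 90/180/270°, horizontal/vertical/both
  flips); inverted predictions are matched per nucleus at IoU > 0.2 and
  fused by strict pixel-level majority vote (> 50%).
* **Evaluation** — object-level precision / recall / F1 with the
  Dice > 0.2 true-positive criterion (`F1 = 2TP/(2TP+FP+FN)`), average Dice
  coefficient over matched pairs (ADC), and the aggregated Jaccard index
  (AJI).
* **Classical baseline segmenter** — GMM nuclei posterior → Otsu →
  distance transform → marker-controlled watershed, so the whole pipeline
  runs and is testable on one CPU. The adapter configuration for an
  external Mask R-CNN backend (anchor ratios 1:1/1:2/2:1, box areas
  8²–128², top-1000 candidates) is recorded in `MaskRCNNConfig`.
* **Synthetic data** — a seeded generator of H&E-like images (elliptical
  nuclei, blobby tissue, controllable stain shift and noise) with exact
  instance ground truth.

## Worked example

```python
import dataclasses
from nucseg.synthetic_data import SynthParams, generate_image
from nucseg.cli import PipelineConfig, segment_image
from nucseg.metrics import evaluate_pair

base = SynthParams(height=256, width=256, n_nuclei=20, noise_std=1.0, seed=7)
template, _ = generate_image(base)
img, gt = generate_image(dataclasses.replace(base, seed=8,
                                             stain_shift=(25.0, -15.0, 10.0)))

config = PipelineConfig(tile_size=160)     # full NucSeg setup
pred = segment_image(img, config, template)
print(evaluate_pair(gt, pred, image_id="demo"))
```

prints

```
MetricRow(image_id='demo', precision=1.0, recall=1.0, f1=1.0,
          adc=0.9993121799691828, aji=0.9989214452633471)
```

i.e. on the easy synthetic regime (20 disjoint, well-separated nuclei, low
noise, a global stain shift corrected by normalization) every nucleus is
found (F1 = 1.0) with near-perfect pixel overlap (ADC, AJI ≈ 0.999).

The same pipeline is available from the shell:

```bash
nucseg simulate --n-images 10 --out-dir data/ --seed 1
nucseg normalize --template t.png --input in.png --output norm.png
nucseg segment --input in.png --output mask.png --template t.png --tta
nucseg evaluate --gt-dir data/gt --pred-dir data/pred --out report.csv
```

The four experimental setups — NucSeg (normalize + TTA), NucSeg-P
(normalize only), NucSeg-N (TTA only), NucSeg-NP (neither) — are reachable
via `--normalize/--no-normalize` and `--tta/--no-tta`.

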