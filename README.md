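# crmap

Saliency mapping for CNNs with a CAM-compatible head (last convolution →
global average pooling → single dense layer). Implements three methods plus
the post-processing and evaluation machinery to compare them:

- **CAM** — dense-weight-weighted sum of last-conv feature maps for one class.
- **Grad-CAM** — feature maps weighted by spatially summed class-score
  gradients, through ReLU. For GAP heads the gradient weights are
  analytically identical to the dense weight columns, so Grad-CAM equals the
  positive part of CAM.
- **CRM (class-selective relevance map)** — scores each spatial element by
  the total squared change across *all* class scores when that element is
  removed from every feature map. Class-discriminative without picking a
  target class; a brute-force leave-one-out oracle is included for
  verification.

On top of the raw maps: max-normalization, relative thresholding (default
20% of max), bilinear/nearest upsampling to input resolution, color overlays,
class-level average-CRM maps with 70%-of-max ROI bounding boxes, and
ROI-size / score-distribution comparison reports.

Everything is exercisable end-to-end on CPU via a built-in synthetic fixture:
a seeded 7-class image generator with ground-truth object masks, and a tiny
pure-NumPy CNN (manual backprop, Adam) that trains to >95% test accuracy in
about a minute.

## CLI

```
crmap generate --out data/                 # synthetic dataset + manifest.csv
crmap train-fixture --out model.npz        # train the fixture CNN (seeded)
crmap map img.png --model model.npz --method crm --out maps/
crmap class-analysis --model model.npz --manifest data/manifest.csv \
      --method cam --method gradcam --method crm --out classes/
crmap report --dumps maps/ --out report.csv   # recompute stats from raw dumps
```

`map` writes, per image and method: a raw map dump (`.npz`), a normalized
heatmap PNG, an overlay PNG, a 0/255 ROI-mask PNG and a JSON sidecar with
predicted class, logits and ROI pixel counts. `class-analysis` additionally
writes per-class average-CRM heatmaps with their ROI bounding boxes and a
CSV/JSON comparison report (columns: class, method, n_images, mean_pixels,
mean_ratio, score_mean, score_std).

## Library sketch

```python
import numpy as np
from crmap import extract, compute_crm, normalize_map, upsample_map, threshold_map
from crmap.synthetic import GeneratorConfig, generate_dataset, train_fixture_model

dataset = generate_dataset(GeneratorConfig())
adapter, metrics = train_fixture_model(dataset)        # seeded, deterministic

img = dataset.splits["test"][0]
fm, head, scores = extract(adapter, img.pixels)        # adapter contract
crm = compute_crm(fm, head)                            # u x v relevance map
nm = upsample_map(normalize_map(crm), adapter.input_shape)
roi = threshold_map(nm, 0.2)                           # pixels > 20% of max
```

Any framework's model can be plugged in by implementing
`crmap.ModelAdapter` (feature maps, dense head, forward logits, optional
gradients); the mapping code never touches framework objects.

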