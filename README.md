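# hlfseg

Trainable membrane segmentation for 2-D electron-microscopy images using
hierarchical level features and a Random Forest.

Serial-section TEM of neural tissue shows bright, textured cell interiors
separated by thin dark membranes; tracing those membranes is the bottleneck
of dense neural-circuit reconstruction. `hlfseg` implements a supervised
pipeline for this task that works at three levels of image structure at
once:

1. **Pixel level** — a bank of 34 filter responses per pixel: 3×3 rank and
   moment filters, Gaussian blurs at σ ∈ {1, 1.5, 2, 3.5, 4, 5, 6}, Sobel,
   Hessian and structure-tensor eigenvalues, difference of Gaussians,
   Kuwahara, Laplacian, Gaussian derivative, 12 ray features and a
   Radon-like feature.
2. **Superpixel level** — the image is oversegmented with SLIC (localized
   k-means in intensity–position space with distance
   D = (d_c/N_c)² + d_s/N_s); each superpixel contributes the mean of every
   pixel channel plus the Shannon entropy of its intensity histogram
   (35 values).
3. **Context level** — mean intensity, mean gradient magnitude and
   intensity variance over the union of a superpixel's first-ring neighbors
   (3 values).

Concatenated, these give a 72-dimensional *hierarchical* feature vector
(34 + 35 + 3). Training uses one randomly selected pixel per superpixel —
pixels inside a superpixel are nearly homogeneous, so this cuts the
training set by two orders of magnitude. A Random Forest (bootstrap
resampling, √72 features per split, no pruning, out-of-bag error estimate)
classifies every pixel as membrane or not; automatic thresholding plus
shape-rule-based removal of compact blobs (organelle false positives)
yields the final binary membrane map. Results are scored with the three
standard challenge metrics: **pixel error** (1 − best F-score over a
threshold sweep), **Rand error** (1 − best F-score of pairwise region
co-clustering) and **warping error** (residual disagreement after
topology-preserving warping of the ground truth, counting only true
topological mistakes).

A seeded synthetic generator produces EM-like sections (Voronoi cells,
dilated dark membranes, per-cell texture, organelle blobs, blur, noise)
with exact ground truth, so the whole pipeline is testable without any
external data.

## Worked example

```python
from hlfseg.config import PipelineConfig
from hlfseg.pipeline import run_pipeline
from hlfseg.synthetic_data import SyntheticSpec, generate_synthetic_em

train, labels = zip(*[generate_synthetic_em(SyntheticSpec(seed=s)) for s in (1, 2)])
test_img, test_gt = generate_synthetic_em(SyntheticSpec(seed=3))

model, results = run_pipeline(list(train), list(labels), [test_img],
                              PipelineConfig(seed=0), test_labels=[test_gt])
r = results[0].report
print(model.oob_error, r.pixel_error, r.rand_error, r.warping_error)
```

Running this (see `examples/04_train_and_segment.py`) prints:

```
out-of-bag error:  0.0032
pixel error:       0.0345 (best threshold 0.65)
rand error:        0.0012
warping error:     0.000000
```

The out-of-bag error (0.3%) says the forest separates the sampled membrane
and non-membrane vectors almost perfectly on this synthetic data. Pixel
error 0.034 means per-pixel F ≈ 0.97 at the best threshold — most residual
disagreement is 1-px boundary jitter. Rand error near 0.001 means the
predicted membranes partition the section into cell regions almost
identically to the ground truth, and warping error 0 means no membrane
breaks or mergers at all survive the geometric tolerance.

The other scripts in `examples/` each exercise one capability: synthesis,
superpixels, feature extraction, and the comparison of hierarchical
features against the pixel-only block.

## Command line

```sh
hlfseg synth --out img.png --gt gt.png --seed 1
hlfseg superpixels --image img.png --out sp.tif --k 1024
hlfseg features --image img.png --gt gt.png --out samples.csv
hlfseg train --images img.png --labels gt.png --out model.bin --trees 100 --seed 7
hlfseg predict --model model.bin --image img.png --out prob.tif
hlfseg evaluate --pred prob.tif --gt gt.png --report report.csv
hlfseg run --train-images train.tif --train-labels gt.tif \
           --test-images test.tif --test-labels test_gt.tif --out-dir out/
```

All parameters live in a YAML config (`--config`); every run writes a
manifest (config echo, seed, channel list) sufficient to reproduce it.

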