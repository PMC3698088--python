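"""Train the Random-Forest membrane classifier and segment a held-out
section, reporting the three challenge metrics.

Pixel error is 1 - best F-score of per-pixel membrane agreement over a
probability-threshold sweep; Rand error compares the induced cell-region
partitions pairwise; warping error counts only topological disagreements
(membrane breaks, mergers) after geometric tolerance is warped away.
Lower is better for all three; 0 is perfect.
"""

from hlfseg.config import PipelineConfig
from hlfseg.pipeline import run_pipeline
from hlfseg.synthetic_data import SyntheticSpec, generate_synthetic_em

train_images, train_masks, test_images, test_masks = [], [], [], []
for seed in (1, 2):
    img, gt = generate_synthetic_em(SyntheticSpec(seed=seed))
    train_images.append(img)
    train_masks.append(gt)
img, gt = generate_synthetic_em(SyntheticSpec(seed=3))
test_images.append(img)
test_masks.append(gt)

config = PipelineConfig(seed=0)
model, results = run_pipeline(
    train_images, train_masks, test_images, config, test_labels=test_masks
)

report = results[0].report
print(f"out-of-bag error:  {model.oob_error:.4f}")
print(f"pixel error:       {report.pixel_error:.4f} "
      f"(best threshold {report.best_threshold_pixel:.2f})")
print(f"rand error:        {report.rand_error:.4f}")
print(f"warping error:     {report.warping_error:.6f}")
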