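"""Feature-level comparison experiments on synthetic data.

The central claim of the hierarchical-feature design is that combining
pixel-level and superpixel-level information beats either level alone:
pixel features are rich but noisy at boundaries, superpixel features adhere
to boundaries but lose detail.  ``feature_level_comparison`` replicates that
comparison at synthetic scale: it trains one forest on the full 72-d
hierarchical vectors and one on the 34-d pixel block only, using identical
images, superpixels and samples, and scores both with the three challenge
metrics on held-out synthetic sections.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import PipelineConfig, SlicConfig
from .features_hlf import FEATURE_NAMES
from .metrics import MetricReport, evaluate
from .pipeline import build_training_table, process_image
from .rf_model import predict_probability_map, train_forest

PIXEL_FEATURE_NAMES = FEATURE_NAMES[:34]


@dataclass
class ComparisonResult:
    """Mean held-out metrics for the two feature sets under one seed."""

    hlf: MetricReport
    pixel_only: MetricReport
    n_train: int
    n_test: int
    seed: int


def _mean_report(reports: list[MetricReport]) -> MetricReport:
    return MetricReport(
        pixel_error=float(np.mean([r.pixel_error for r in reports])),
        rand_error=float(np.mean([r.rand_error for r in reports])),
        warping_error=float(np.mean([r.warping_error for r in reports])),
        best_threshold_pixel=float(np.mean([r.best_threshold_pixel for r in reports])),
        best_threshold_rand=float(np.mean([r.best_threshold_rand for r in reports])),
    )


def feature_level_comparison(
    seed: int,
    n_train: int = 5,
    n_test: int = 5,
    size: int = 256,
    superpixel_size: float | None = None,
    n_trees: int = 100,
    n_thresholds: int = 64,
) -> ComparisonResult:
    """Train and score HLF vs pixel-only forests on synthetic sections.

    ``superpixel_size`` sets the SLIC grid interval s (superpixel count
    size^2 / s^2); by default the package's area-scaled superpixel count is
    used.  Both classifiers share every upstream artifact, so the only
    difference is the feature blocks the forest sees.
    """
    from .synthetic_data import SyntheticSpec, generate_synthetic_em

    spec = SyntheticSpec(height=size, width=size, seed=seed)
    images, masks = [], []
    for i in range(n_train + n_test):
        img, gt = generate_synthetic_em(replace(spec, seed=seed * 10_000 + i))
        images.append(img)
        masks.append(gt)

    if superpixel_size is not None:
        k = max(1, round(size * size / superpixel_size**2))
        config = PipelineConfig(seed=seed, slic=SlicConfig(k=k))
    else:
        config = PipelineConfig(seed=seed)
    config.forest.n_trees = n_trees

    train_feats = [process_image(img, config) for img in images[:n_train]]
    table = build_training_table(
        images[:n_train], masks[:n_train], config, features=train_feats
    )
    model_hlf = train_forest(table, n_trees=n_trees, seed=seed)
    model_px = train_forest(
        table, n_trees=n_trees, seed=seed, feature_names=PIXEL_FEATURE_NAMES
    )

    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    reports_hlf, reports_px = [], []
    for img, gt in zip(images[n_train:], masks[n_train:]):
        feats = process_image(img, config)
        prob_hlf = predict_probability_map(
            model_hlf, feats.image, feats.superpixels, feats.stack,
            feats.spx_feats, feats.ctx,
        )
        # pixel-only: same dense pixel block, no superpixel/context columns
        pixel_block = feats.stack.reshape(feats.stack.shape[0], -1).T
        prob_px = model_px.predict_proba_membrane(pixel_block).reshape(img.shape)
        reports_hlf.append(evaluate(prob_hlf, gt, thresholds))
        reports_px.append(evaluate(prob_px, gt, thresholds))

    return ComparisonResult(
        hlf=_mean_report(reports_hlf),
        pixel_only=_mean_report(reports_px),
        n_train=n_train,
        n_test=n_test,
        seed=seed,
    )
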