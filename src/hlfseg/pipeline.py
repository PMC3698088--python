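"""End-to-end orchestration of the membrane-segmentation pipeline.

One image flows through: preprocessing -> SLIC oversegmentation -> pixel
feature bank -> superpixel / context feature blocks -> (training) one
random sample per superpixel, or (inference) dense per-pixel classification
-> probability map -> postprocessed binary membrane map -> metrics against
ground truth when available.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .features_hlf import (
    FEATURE_NAMES,
    N_FEATURES,
    assemble_hlf,
    build_adjacency,
    context_features,
    select_samples,
    superpixel_block,
)
from .features_pixel import CHANNEL_NAMES, compute_pixel_features
from .metrics import MetricReport, evaluate
from .postprocess import postprocess as _postprocess
from .preprocess import preprocess as _preprocess
from .rf_model import ForestModel, predict_probability_map, train_forest
from .slic import oversegment

log = logging.getLogger("hlfseg")


@dataclass
class ImageFeatures:
    """All per-image intermediates needed for sampling or dense prediction."""

    image: np.ndarray  # preprocessed image
    superpixels: np.ndarray
    stack: np.ndarray  # 34 x H x W
    spx_feats: np.ndarray  # K x 35
    ctx: np.ndarray  # K x 3


def process_image(img: np.ndarray, config: PipelineConfig) -> ImageFeatures:
    """Run the feature half of the pipeline on one raw image."""
    pp = config.preprocess
    enhanced = _preprocess(img, equalize=pp.equalize, sigma=pp.sigma, n_levels=pp.n_levels)
    sl = config.slic
    sp = oversegment(
        enhanced,
        k=sl.resolve_k(enhanced.size),
        compactness=sl.compactness,
        n_iters=sl.n_iters,
        distance_form=sl.distance_form,
        min_size=sl.min_size,
    )
    stack = compute_pixel_features(enhanced)
    adj = build_adjacency(sp)
    spx = superpixel_block(enhanced, stack, sp, n_bins=config.hlf.entropy_bins)
    ctx = context_features(enhanced, sp, adj)
    log.info("processed image: %d superpixels", sp.max() + 1)
    return ImageFeatures(enhanced, sp, stack, spx, ctx)


def build_training_table(
    images: list[np.ndarray],
    labels: list[np.ndarray],
    config: PipelineConfig,
    features: list[ImageFeatures] | None = None,
) -> pd.DataFrame:
    """Representative-sample table over all training images."""
    tables = []
    for i, (img, gt) in enumerate(zip(images, labels)):
        if np.asarray(img).shape != np.asarray(gt).shape:
            raise ValueError(f"image {i} and its label image have different shapes")
        feats = features[i] if features is not None else process_image(img, config)
        samples = select_samples(feats.superpixels, gt, seed=config.seed + i)
        table = assemble_hlf(
            feats.stack, feats.superpixels, feats.spx_feats, feats.ctx, samples, gt=gt
        )
        table.insert(0, "image_id", i)
        tables.append(table)
        log.info(
            "image %d: %d samples, membrane fraction %.3f",
            i, len(table), table["label"].mean(),
        )
    return pd.concat(tables, ignore_index=True)


def train_pipeline(
    images: list[np.ndarray], labels: list[np.ndarray], config: PipelineConfig
) -> ForestModel:
    table = build_training_table(images, labels, config)
    return train_forest(table, n_trees=config.forest.n_trees, seed=config.seed)


@dataclass
class ImageResult:
    probability: np.ndarray
    binary: np.ndarray
    report: MetricReport | None


def predict_image(
    model: ForestModel,
    img: np.ndarray,
    config: PipelineConfig,
    gt: np.ndarray | None = None,
    features: ImageFeatures | None = None,
) -> ImageResult:
    feats = features if features is not None else process_image(img, config)
    prob = predict_probability_map(
        model, feats.image, feats.superpixels, feats.stack, feats.spx_feats, feats.ctx
    )
    binary = _postprocess(
        prob,
        method=config.postprocess.method,
        rules=config.postprocess.rules,
        max_iters=config.postprocess.max_iters,
    )
    report = None
    if gt is not None:
        thresholds = np.linspace(0.0, 1.0, config.metrics.n_thresholds)
        report = evaluate(prob, gt, thresholds, tolerance_px=config.metrics.tolerance_px)
    return ImageResult(probability=prob, binary=binary, report=report)


def run_pipeline(
    train_images: list[np.ndarray],
    train_labels: list[np.ndarray],
    test_images: list[np.ndarray],
    config: PipelineConfig,
    test_labels: list[np.ndarray] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[ForestModel, list[ImageResult]]:
    """Full train-and-evaluate run; optionally writes all stage outputs plus
    a manifest sufficient to reproduce the run."""
    if not train_images:
        raise ValueError("at least one training image with labels is required")
    model = train_pipeline(train_images, train_labels, config)
    results = []
    for i, img in enumerate(test_images):
        gt = test_labels[i] if test_labels is not None else None
        results.append(predict_image(model, img, config, gt=gt))

    if out_dir is not None:
        from .io import write_image, write_probability_map

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, res in enumerate(results):
            write_probability_map(out / f"prob_{i:03d}.tif", res.probability)
            write_image(out / f"seg_{i:03d}.png", res.binary.astype(np.float64))
            if res.report is not None:
                rows.append(
                    {
                        "image": i,
                        "pixel_error": res.report.pixel_error,
                        "rand_error": res.report.rand_error,
                        "warping_error": res.report.warping_error,
                        "best_threshold_pixel": res.report.best_threshold_pixel,
                        "best_threshold_rand": res.report.best_threshold_rand,
                    }
                )
        if rows:
            pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "n_features": N_FEATURES,
            "feature_names": list(FEATURE_NAMES),
            "channel_names": list(CHANNEL_NAMES),
            "oob_error": model.oob_error,
            "n_train_images": len(train_images),
            "n_test_images": len(test_images),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return model, results
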