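"""Random-Forest membrane classifier over hierarchical feature vectors.

Each tree is grown on a bootstrap resample of the training samples, with a
random subset of sqrt(72) ~ 8 features considered at every split and no
pruning; the out-of-bag samples give an internal generalization estimate, so
no held-out validation set is needed.  The classifier is pluggable: anything
exposing the scikit-learn ``fit`` / ``predict_proba`` contract can stand in
for the forest (used for classifier comparisons).
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features_hlf import FEATURE_NAMES


@dataclass
class ForestModel:
    """A trained membrane classifier plus the feature layout it expects."""

    classifier: object
    feature_names: tuple[str, ...]
    oob_error: float | None = None
    n_trees: int | None = None
    seed: int | None = None
    membrane_class_index: int = field(default=1)

    def predict_proba_membrane(self, X: np.ndarray) -> np.ndarray:
        """Membrane-class probability for each row of ``X``."""
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature layout mismatch: model expects {len(self.feature_names)} "
                f"features, got {X.shape[1]}"
            )
        proba = self.classifier.predict_proba(X)
        return proba[:, self.membrane_class_index]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ForestModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def train_forest(
    samples: pd.DataFrame,
    n_trees: int = 100,
    seed: int = 0,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> ForestModel:
    """Train the Random Forest on a sample table.

    ``samples`` must carry the feature columns plus a binary ``label`` column
    (1 = membrane).  Both classes must be present.  The out-of-bag error is
    stored on the returned model.
    """
    missing = [c for c in feature_names if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table is missing feature columns: {missing[:3]}...")
    if "label" not in samples.columns:
        raise ValueError("sample table has no 'label' column")
    y = samples["label"].to_numpy()
    classes = np.unique(y)
    if len(samples) < 2 or classes.size < 2:
        raise ValueError(
            "training requires at least 2 samples with both classes present; "
            f"got {len(samples)} samples with classes {classes.tolist()}"
        )
    X = samples[list(feature_names)].to_numpy(dtype=np.float64)

    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # tiny bootstrap samples can leave a few rows never out-of-bag
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        clf.fit(X, y)
    membrane_idx = int(np.flatnonzero(clf.classes_ == 1)[0])
    return ForestModel(
        classifier=clf,
        feature_names=tuple(feature_names),
        oob_error=float(1.0 - clf.oob_score_),
        n_trees=n_trees,
        seed=seed,
        membrane_class_index=membrane_idx,
    )


def dense_feature_matrix(
    stack: np.ndarray,
    sp: np.ndarray,
    spx_feats: np.ndarray,
    ctx: np.ndarray,
) -> np.ndarray:
    """72-d feature vector for every pixel: own pixel block plus the blocks
    of the superpixel it belongs to.  Shape (H*W, 72)."""
    stack = np.asarray(stack, dtype=np.float64)
    sp = np.asarray(sp)
    flat_sp = sp.ravel()
    pixel_block = stack.reshape(stack.shape[0], -1).T
    return np.concatenate(
        [pixel_block, spx_feats[flat_sp], ctx[flat_sp]], axis=1
    )


def predict_probability_map(
    model: ForestModel,
    img: np.ndarray,
    sp: np.ndarray,
    stack: np.ndarray,
    spx_feats: np.ndarray,
    ctx: np.ndarray,
    chunk: int = 65536,
) -> np.ndarray:
    """Per-pixel membrane probability map for a whole image.

    Every pixel is classified on its own 72-d vector; pixels of one
    superpixel share the superpixel and context blocks, so two pixels with
    identical pixel blocks in the same superpixel get identical
    probabilities.
    """
    img = np.asarray(img)
    X = dense_feature_matrix(stack, sp, spx_feats, ctx)
    if X.shape[1] != len(model.feature_names):
        raise ValueError("feature layout mismatch between model and inputs")
    prob = np.empty(X.shape[0], dtype=np.float64)
    for start in range(0, X.shape[0], chunk):
        prob[start : start + chunk] = model.predict_proba_membrane(
            X[start : start + chunk]
        )
    return prob.reshape(img.shape)
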