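"""Gradient-boosted cell classification on the 19 morphometry features."""

from __future__ import annotations

import numpy as np
from xgboost import XGBClassifier

from .morphometry import MORPHO_FEATURE_NAMES

__all__ = ["MorphoGbt", "train_morpho_gbt", "classify_morpho"]


class DataError(ValueError):
    pass


class MorphoGbt:
    """Wraps an XGBoost classifier plus its label vocabulary."""

    def __init__(self, booster: XGBClassifier, classes: list[str]):
        self.booster = booster
        self.classes = list(classes)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        if features.shape[1] != len(MORPHO_FEATURE_NAMES):
            raise ValueError(
                f"expected {len(MORPHO_FEATURE_NAMES)} features, "
                f"got {features.shape[1]}")
        return self.booster.predict_proba(features)


def train_morpho_gbt(features, labels, seed: int = 0,
                     n_estimators: int = 200, max_depth: int = 4,
                     learning_rate: float = 0.2):
    """Fit the morphology classifier; deterministic given ``seed``.

    ``reg_lambda`` and ``min_child_weight`` are zero so splits and leaf
    values depend only on gradient/hessian ratios (the small 19-feature space
    is regularised through depth instead); predictions are then exactly
    invariant under dataset duplication.

    Returns ``(model, training accuracy)``.
    """
    x = np.asarray([np.asarray(f, dtype=float) for f in features])
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise DataError("need at least 2 classes to train")
    yi = np.searchsorted(np.array(classes), y)
    booster = XGBClassifier(
        n_estimators=n_estimators, max_depth=max_depth,
        learning_rate=learning_rate, reg_lambda=0.0, min_child_weight=0.0,
        tree_method="exact", n_jobs=1, random_state=seed)
    booster.fit(x, yi)
    acc = float((booster.predict(x) == yi).mean())
    return MorphoGbt(booster, classes), acc


def classify_morpho(features: np.ndarray, model: MorphoGbt):
    """Classify one 19-feature vector.

    Returns ``(class id, probability)``; argmax with lowest-index tie-break.
    """
    p = model.predict_proba(np.asarray(features, dtype=float)[None, :])[0]
    k = int(np.argmax(p))
    return model.classes[k], float(p[k])
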