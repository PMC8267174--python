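"""Slide-level classification: a gradient-boosted decision-tree ensemble
(LightGBM) over the 36 heatmap statistics.

Booster defaults are pinned for reproducibility: 100 trees, 31 leaves,
learning rate 0.1, single thread, deterministic, and min_child_samples=2 so
that trees can split at the slide counts typical of desk-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, N_FEATURES, HeatmapFeatureVector

DEFAULT_PARAMS = {
    "n_estimators": 100,
    "num_leaves": 31,
    "learning_rate": 0.1,
    "min_child_samples": 2,
    "n_jobs": 1,
    "deterministic": True,
    "force_row_wise": True,
    "verbosity": -1,
}


@dataclass
class SlidePrediction:
    slide_id: str
    p_cancerous: float
    predicted_label: str  # "normal" | "cancerous"


def _to_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, HeatmapFeatureVector):
        features = [features]
    if isinstance(features, pd.DataFrame):
        ids = features["slide_id"].tolist() if "slide_id" in features else \
            [str(i) for i in range(len(features))]
        X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
        return X, ids
    X = np.vstack([np.asarray(f.values, dtype=float) if
                   isinstance(f, HeatmapFeatureVector) else np.asarray(f, dtype=float)
                   for f in features])
    ids = [f.slide_id if isinstance(f, HeatmapFeatureVector) else str(i)
           for i, f in enumerate(features)]
    return X, ids


def train_slide_classifier(features, labels, params: dict | None = None,
                           seed: int = 0) -> lgb.LGBMClassifier:
    """Fit the booster on 36-feature slide vectors.

    labels are 0 (normal) / 1 (cancerous) or the label strings. Fails
    explicitly on single-class input. Deterministic given seed (single
    threaded)."""
    X, _ = _to_matrix(features)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
    y = np.asarray([1 if lab in (1, "cancerous", "carcinoma") else 0
                    for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both slide classes")
    merged = {**DEFAULT_PARAMS, **(params or {}), "random_state": seed}
    model = lgb.LGBMClassifier(**merged)
    model.fit(X, y, feature_name=list(FEATURE_NAMES))
    return model


def predict_slide(model: lgb.LGBMClassifier, features,
                  threshold: float = 0.5) -> list[SlidePrediction]:
    """Probability of cancer per slide, thresholded into a label
    (p >= threshold -> cancerous)."""
    X, ids = _to_matrix(features)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
    probs = model.predict_proba(
        pd.DataFrame(X, columns=list(FEATURE_NAMES)))[:, 1]
    return [SlidePrediction(slide_id=sid, p_cancerous=float(p),
                            predicted_label="cancerous" if p >= threshold else "normal")
            for sid, p in zip(ids, probs)]


def feature_importances(model: lgb.LGBMClassifier) -> list[tuple[str, float]]:
    """All 36 features with their total split gain, sorted descending;
    ties break by feature index. Raises on an unfitted model."""
    if not hasattr(model, "booster_"):
        raise RuntimeError("model is not trained")
    gains = model.booster_.feature_importance(importance_type="gain")
    order = sorted(range(N_FEATURES), key=lambda i: (-gains[i], i))
    return [(FEATURE_NAMES[i], float(gains[i])) for i in order]


def save_model(model: lgb.LGBMClassifier, path: str | Path,
               metadata: dict | None = None) -> None:
    """LightGBM text model format plus a JSON sidecar."""
    path = Path(path)
    model.booster_.save_model(str(path.with_suffix(".txt")))
    path.with_suffix(".json").write_text(json.dumps(
        {"params": {k: v for k, v in model.get_params().items()
                    if isinstance(v, (int, float, str, bool, type(None)))},
         **(metadata or {})}, indent=2))


def predictions_to_csv(predictions: list[SlidePrediction], path: str | Path,
                       true_labels: dict[str, str] | None = None) -> pd.DataFrame:
    rows = [{"slide_id": p.slide_id, "p_cancerous": p.p_cancerous,
             "predicted_label": p.predicted_label,
             "true_label": (true_labels or {}).get(p.slide_id)}
            for p in predictions]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
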