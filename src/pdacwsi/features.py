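"""The 36 heatmap summary statistics driving slide-level classification.

For each slide the patch classifier yields a grid of (p_normal, p_tumor)
pairs. Features 1-9 are mean, variance, standard deviation, median, mode,
minimum, maximum, range and sum of the normal probabilities; features 10-18
are the same nine statistics of the tumor probabilities. Features 19-34
are the per-class patch counts N_p over eight high-confidence probability
bands partitioning (0.5, 1]. Feature 35 is the numeric label of the class
with the larger mean probability and feature 36 the label of the class
winning the per-patch argmax count (labels: 0 = normal, 1 = tumor; ties go
to tumor — the pipeline errs toward sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heatmap import ProbabilityHeatmap

#: (lo, hi] probability bands, highest-confidence first; disjoint, and their
#: union is (0.5, 1].
BANDS: tuple[tuple[float, float], ...] = (
    (0.999, 1.0),
    (0.99, 0.999),
    (0.95, 0.99),
    (0.9, 0.95),
    (0.8, 0.9),
    (0.7, 0.8),
    (0.6, 0.7),
    (0.5, 0.6),
)

_STATS = ("mean", "variance", "std", "median", "mode", "min", "max", "range", "sum")

#: column names, in feature order f1..f36
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"normal_{s}" for s in _STATS]
    + [f"tumor_{s}" for s in _STATS]
    + [f"np_{cls}_gt{lo}" for lo, _ in BANDS for cls in ("normal", "tumor")]
    + ["argmax_mean_class", "majority_class"]
)

N_FEATURES = 36


def band_of(p: float) -> int | None:
    """Index into BANDS of the unique band containing p, or None for
    p <= 0.5 (no band). Band edges belong to the lower band: the top band
    is strictly P > 0.999."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    for i, (lo, hi) in enumerate(BANDS):
        if lo < p <= hi:
            return i
    return None


def _mode(values: np.ndarray) -> float:
    """Most frequent value after rounding to 2 decimals; ties break to the
    smallest value (a convention — the mode of a continuous sample needs
    one)."""
    rounded = np.round(values, 2)
    uniq, counts = np.unique(rounded, return_counts=True)
    return float(uniq[np.argmax(counts)])  # np.unique sorts, argmax -> smallest


def _nine_stats(values: np.ndarray) -> list[float]:
    v = float(np.var(values))
    return [float(np.mean(values)), v, float(np.sqrt(v)),
            float(np.median(values)), _mode(values),
            float(np.min(values)), float(np.max(values)),
            float(np.max(values) - np.min(values)), float(np.sum(values))]


@dataclass
class HeatmapFeatureVector:
    slide_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_NAMES), name=self.slide_id)


def extract_features(heatmap: ProbabilityHeatmap,
                     include_background: bool = False) -> HeatmapFeatureVector:
    """Compute the 36 statistics over the heatmap's counted cells.

    Background cells are excluded unless include_background is set (white
    border regions would otherwise swamp the slide statistics). Fails
    explicitly when no counted cell remains.
    """
    cells = heatmap.grid.reshape(-1, 2)
    if not include_background:
        cells = cells[~heatmap.background.reshape(-1)]
    if len(cells) == 0:
        raise ValueError("no counted cells after background exclusion")
    p_normal, p_tumor = cells[:, 0], cells[:, 1]

    values = _nine_stats(p_normal) + _nine_stats(p_tumor)
    for lo, hi in BANDS:
        for p in (p_normal, p_tumor):
            values.append(float(np.sum((lo < p) & (p <= hi))))
    # f35: class with the larger mean probability; tie -> tumor (label 1)
    values.append(1.0 if np.mean(p_tumor) >= np.mean(p_normal) else 0.0)
    # f36: class with the most patches under per-cell argmax; ties -> tumor
    tumor_cells = int(np.sum(p_tumor >= p_normal))
    values.append(1.0 if tumor_cells >= len(cells) - tumor_cells else 0.0)
    return HeatmapFeatureVector(slide_id=heatmap.slide_id,
                                values=np.array(values))


def features_to_frame(vectors: list[HeatmapFeatureVector]) -> pd.DataFrame:
    """One row per slide, columns slide_id + the 36 named features."""
    df = pd.DataFrame([v.as_series() for v in vectors])
    df.insert(0, "slide_id", [v.slide_id for v in vectors])
    return df.reset_index(drop=True)
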