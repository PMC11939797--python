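"""Faithfulness evaluation of attributions: sufficiency, comprehensiveness,
sensitivity, and windowed effectiveness curves.

For record x_i evaluated on class j, the top-k% rationale r_ik is the set of
features with the highest attribution. The three criteria average the
probability change over removal levels B (percent of features):

    sufficiency        = mean_k [ p_j(x_i) - p_j(rationale kept only) ]
    comprehensiveness  = mean_k [ p_j(x_i) - p_j(rationale removed) ]
    sensitivity        = mean_k [ p_j(x_i) - p_j(rationale + Gaussian noise) ]

Removal sets features to a baseline value (0 by default — the natural
absence value for TF-IDF or topic features). Per-class values average over
the records whose evaluation class is that class; report averages are
unweighted means across classes. The window curves slide a fixed-size
window down the importance ranking and measure the mean absolute
probability distance per window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FaithfulnessConfig",
    "select_rationale",
    "sufficiency",
    "comprehensiveness",
    "sensitivity",
    "faithfulness_report",
    "window_curves",
    "FaithfulnessReport",
    "evaluate_faithfulness",
]

DEFAULT_B = (1, 5, 10, 20, 50)
SIGMA_RANGE_FRACTION = 0.09
METRICS = ("sufficiency", "comprehensiveness", "sensitivity")


@dataclass(frozen=True)
class FaithfulnessConfig:
    """Knobs of the faithfulness suite.

    ``sigma=None`` defaults to 0.09 × the per-feature value range of the
    evaluated records (matching the gradient-SHAP noise convention).
    """

    b_levels: tuple = DEFAULT_B
    baseline: float = 0.0
    sigma: float | None = None
    window: int = 5
    max_windows: int | None = None
    seed: int = 0

    def __post_init__(self):
        b = tuple(self.b_levels)
        object.__setattr__(self, "b_levels", b)
        if not b or any(not (0 < k <= 100) for k in b) or any(y <= x for x, y in zip(b, b[1:])):
            raise ValueError("b_levels must be strictly increasing within (0, 100]")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def select_rationale(attribution: np.ndarray, k: float) -> np.ndarray:
    """Indices of the top k% features by descending importance (ties by index).

    The rationale size is ceil(k/100 × F), never below 1.
    """
    attribution = np.asarray(attribution, dtype=float)
    if attribution.size == 0:
        raise ValueError("attribution vector is empty")
    if not (0 < k <= 100):
        raise ValueError("k must lie in (0, 100]")
    size = max(1, math.ceil(k / 100.0 * attribution.size))
    order = np.argsort(-attribution, kind="stable")
    return order[:size]


def _sigma_vector(X: np.ndarray, cfg: FaithfulnessConfig) -> np.ndarray:
    if cfg.sigma is not None:
        return np.full(X.shape[1], float(cfg.sigma))
    return SIGMA_RANGE_FRACTION * (X.max(axis=0) - X.min(axis=0))


def _class_groups(labels):
    labels = np.asarray([str(l) for l in labels])
    return {c: np.flatnonzero(labels == c) for c in sorted(set(labels))}


def _per_class(model, X, labels, attributions, cfg, mode: str, absolute: bool = False) -> dict:
    X = np.asarray(X, dtype=float)
    attributions = np.asarray(attributions, dtype=float)
    if attributions.shape != X.shape:
        raise ValueError("attributions must be one vector per record")
    sigma = _sigma_vector(X, cfg) if mode == "sensitivity" else None
    rng = np.random.default_rng(cfg.seed)
    out = {}
    base_proba = model.predict_proba(X)
    for c, idx in _class_groups(labels).items():
        j = model.class_index(c)
        level_means = []
        for k in cfg.b_levels:
            altered = X[idx].copy()
            for row, i in enumerate(idx):
                r = select_rationale(attributions[i], k)
                if mode == "sufficiency":
                    kept = np.full(X.shape[1], cfg.baseline)
                    kept[r] = X[i, r]
                    altered[row] = kept
                elif mode == "comprehensiveness":
                    altered[row, r] = cfg.baseline
                elif mode == "sensitivity":
                    altered[row, r] = X[i, r] + rng.normal(0.0, 1.0, size=r.size) * sigma[r]
                else:  # pragma: no cover
                    raise ValueError(mode)
            diff = base_proba[idx, j] - model.predict_proba(altered)[:, j]
            level_means.append(np.abs(diff).mean() if absolute else diff.mean())
        out[c] = float(np.mean(level_means))
    return out


def sufficiency(model, records, labels, attributions, cfg: FaithfulnessConfig) -> dict:
    """Per-class mean drop when the input is reduced to its rationale only."""
    return _per_class(model, records, labels, attributions, cfg, "sufficiency")


def comprehensiveness(model, records, labels, attributions, cfg: FaithfulnessConfig) -> dict:
    """Per-class mean drop when the rationale is removed from the input."""
    return _per_class(model, records, labels, attributions, cfg, "comprehensiveness")


def sensitivity(model, records, labels, attributions, cfg: FaithfulnessConfig) -> dict:
    """Per-class mean change when Gaussian noise hits only rationale features."""
    return _per_class(model, records, labels, attributions, cfg, "sensitivity")


@dataclass(frozen=True)
class FaithfulnessReport:
    per_class: dict  # metric -> {class -> value}
    averages: dict  # metric -> unweighted mean across classes
    curves: dict = field(default_factory=dict)  # (class, metric) -> np.ndarray

    def to_frame(self, method: str = "") -> pd.DataFrame:
        rows = []
        for metric, values in self.per_class.items():
            row = {"method": method, "criterion": metric}
            row.update({c: round(v, 3) for c, v in values.items()})
            row["Average"] = round(self.averages[metric], 3)
            rows.append(row)
        return pd.DataFrame(rows)

    def curves_frame(self, method: str = "") -> pd.DataFrame:
        recs = [
            {"method": method, "class": c, "criterion": m, "window": t + 1, "value": float(v)}
            for (c, m), vals in self.curves.items()
            for t, v in enumerate(vals)
        ]
        return pd.DataFrame(recs, columns=["method", "class", "criterion", "window", "value"])


def faithfulness_report(per_class: dict, curves: dict | None = None) -> FaithfulnessReport:
    """Aggregate per-class values; the average is their exact unweighted mean."""
    class_sets = {frozenset(v) for v in per_class.values()}
    if len(class_sets) > 1:
        raise ValueError("all metrics must cover the same class set")
    # sum in sorted class order so the mean is bit-identical however the dict was built
    averages = {
        m: float(np.mean([v[c] for c in sorted(v)])) for m, v in per_class.items()
    }
    return FaithfulnessReport(per_class, averages, dict(curves or {}))


def window_curves(model, records, labels, attributions, cfg: FaithfulnessConfig) -> dict:
    """Mean |probability distance| per importance window, per metric per class.

    Window t covers features ranked (t-1)w+1 … tw; there are
    ceil(F / w) windows (the last possibly truncated), capped by
    ``cfg.max_windows``.
    """
    X = np.asarray(records, dtype=float)
    attributions = np.asarray(attributions, dtype=float)
    n_features = X.shape[1]
    w = cfg.window
    if n_features < w:
        warnings.warn("fewer features than one window; using a single truncated window", stacklevel=2)
    n_windows = max(1, math.ceil(n_features / w))
    if cfg.max_windows is not None:
        n_windows = min(n_windows, cfg.max_windows)
    sigma = _sigma_vector(X, cfg)
    base_proba = model.predict_proba(X)
    ranks = np.argsort(-attributions, axis=1, kind="stable")
    curves = {}
    for c, idx in _class_groups(labels).items():
        j = model.class_index(c)
        for metric in METRICS:
            rng = np.random.default_rng(cfg.seed)
            vals = np.empty(n_windows)
            for t in range(n_windows):
                altered = X[idx].copy()
                for row, i in enumerate(idx):
                    win = ranks[i, t * w : (t + 1) * w]
                    if metric == "sufficiency":
                        kept = np.full(n_features, cfg.baseline)
                        kept[win] = X[i, win]
                        altered[row] = kept
                    elif metric == "comprehensiveness":
                        altered[row, win] = cfg.baseline
                    else:
                        altered[row, win] = X[i, win] + rng.normal(0.0, 1.0, size=win.size) * sigma[win]
                vals[t] = np.abs(base_proba[idx, j] - model.predict_proba(altered)[:, j]).mean()
            curves[(c, metric)] = vals
    return curves


def evaluate_faithfulness(model, records, labels, attributions, cfg: FaithfulnessConfig | None = None):
    """Run all three criteria plus window curves and assemble the report."""
    cfg = cfg or FaithfulnessConfig()
    per_class = {
        "sufficiency": sufficiency(model, records, labels, attributions, cfg),
        "comprehensiveness": comprehensiveness(model, records, labels, attributions, cfg),
        "sensitivity": sensitivity(model, records, labels, attributions, cfg),
    }
    curves = window_curves(model, records, labels, attributions, cfg)
    return faithfulness_report(per_class, curves)
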