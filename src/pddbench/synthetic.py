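"""Synthetic zero-inflated feature tables with planted class-conditional structure.

The generator emulates the statistical shape of L2-normalized TF-IDF (or
topic-probability) tables: most entries are exactly zero, positive entries
are small, and each class shifts a disjoint set of informative features
upward. The planted (class, feature) associations form the ground truth for
recovery, clustering, attribution, and faithfulness testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_features import FeatureTable
from .knowledge_base import KnowledgeBase

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "recovery_score"]

BACKGROUND_MEAN = 0.02
BACKGROUND_SD = 0.01


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic benchmark.

    Background feature values are 0 with probability ``zero_inflation`` and
    |Normal(0.02, 0.01)| otherwise. An informative feature of a record's
    class has its zero probability reduced to a quarter and its mean shifted
    up by ``effect_size`` (0.05 = five background standard deviations).
    """

    n_records: int = 2000
    n_classes: int = 4
    n_features: int = 30
    n_informative: int = 3
    effect_size: float = 0.05
    zero_inflation: float = 0.6
    prevalences: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.n_classes * self.n_informative > self.n_features:
            raise ValueError("informative features × classes exceed n_features")
        if self.prevalences is not None:
            p = tuple(float(x) for x in self.prevalences)
            if len(p) != self.n_classes or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("prevalences must have one entry per class and sum to 1")
            object.__setattr__(self, "prevalences", p)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: per class, its informative features and shift direction."""

    informative: dict  # class value -> tuple of feature names
    direction: str = "high"

    def planted_pairs(self):
        return {(c, f) for c, feats in self.informative.items() for f in feats}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"direction": self.direction, "informative": {c: list(v) for c, v in self.informative.items()}}, fh, indent=2)


def generate(spec: SyntheticSpec):
    """Draw a labeled feature table and its ground truth, deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    classes = [f"c{k}" for k in range(spec.n_classes)]
    features = tuple(f"f{j:03d}" for j in range(spec.n_features))
    prev = (
        np.full(spec.n_classes, 1.0 / spec.n_classes)
        if spec.prevalences is None
        else np.asarray(spec.prevalences)
    )
    labels = rng.choice(spec.n_classes, size=spec.n_records, p=prev)
    informative = {
        classes[k]: features[k * spec.n_informative : (k + 1) * spec.n_informative]
        for k in range(spec.n_classes)
    }
    zero = rng.random((spec.n_records, spec.n_features))
    magnitude = np.abs(rng.normal(BACKGROUND_MEAN, BACKGROUND_SD, (spec.n_records, spec.n_features)))
    shift = np.zeros((spec.n_records, spec.n_features))
    zero_thresh = np.full((spec.n_records, spec.n_features), spec.zero_inflation)
    if spec.effect_size > 0:  # at zero effect the table is a pure null: labels independent of features
        for k in range(spec.n_classes):
            rows = labels == k
            cols = np.arange(k * spec.n_informative, (k + 1) * spec.n_informative)
            shift[np.ix_(rows, cols)] = spec.effect_size
            zero_thresh[np.ix_(rows, cols)] = spec.zero_inflation / 4.0
    values = np.where(zero < zero_thresh, 0.0, magnitude + shift)
    record_ids = tuple(f"r{i:05d}" for i in range(spec.n_records))
    table = FeatureTable(record_ids, features, values, tuple(classes[k] for k in labels))
    return table, GroundTruth(informative)


def _top_bin_per_attribute(kb: KnowledgeBase) -> dict:
    top = {}
    for av in kb.av_catalog:
        if av.is_label:
            continue
        top[av.attribute] = max(top.get(av.attribute, 0), av.bin_index)
    return top


def recovery_score(kb: KnowledgeBase, truth: GroundTruth):
    """Recall and precision of the planted class–feature associations.

    A planted (class, feature) pair counts as recovered when some pattern
    row ties that class to the feature's shifted-direction AV (the top bin,
    for upward shifts). Asserted pairs are all distinct (row class, feature)
    pairs whose AV is in the shifted direction.
    """
    planted = truth.planted_pairs()
    top_bin = _top_bin_per_attribute(kb)
    asserted = set()
    for row in kb.rows:
        if row.class_value is None:
            continue
        for fa in row.feature_avs:
            if kb.av_catalog[fa.av_index].bin_index == top_bin.get(fa.attribute, -1):
                asserted.add((row.class_value, fa.attribute))
    recovered = planted & asserted
    recall = len(recovered) / len(planted) if planted else float("nan")
    precision = len(recovered) / len(asserted) if asserted else float("nan")
    return recall, precision
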