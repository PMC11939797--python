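"""Pattern-match classification against the knowledge base, plus metrics.

A record is assigned to the class with the most associated patterns: its
score for class c is the total number of feature AVs it matches across the
knowledge-base rows tied to c. Normalized scores double as class
probabilities so that ROC-AUC is computable for the white-box model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    balanced_accuracy_score,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .discretize import EventMatrix, apply_bins, fit_bins
from .disentangle import build_spaces
from .io_features import FeatureTable
from .knowledge_base import KnowledgeBase, assemble_kb, coverage_counts
from .srm import DEFAULT_TAU, build_srm

__all__ = [
    "ClassScores",
    "MetricsReport",
    "score_records",
    "evaluate_metrics",
    "class_distribution",
    "PDDClassifier",
]


@dataclass(frozen=True)
class ClassScores:
    classes: tuple
    scores: np.ndarray  # (n_records, n_classes) matched fraction of each class's pattern AVs
    probabilities: np.ndarray  # rows sum to 1 (uniform when all scores are 0)
    assigned: tuple  # predicted class per record
    record_ids: tuple
    raw_scores: np.ndarray | None = None  # summed matched-AV coverage before normalization


@dataclass(frozen=True)
class MetricsReport:
    macro_roc_auc: float
    micro_roc_auc: float
    macro_f1: float
    micro_f1: float
    balanced_accuracy: float
    macro_precision: float
    micro_precision: float
    macro_recall: float
    micro_recall: float

    def to_frame(self, name: str = "model") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Model": name,
                    "Macro ROC-AUC": self.macro_roc_auc,
                    "Micro ROC-AUC": self.micro_roc_auc,
                    "Macro F1": self.macro_f1,
                    "Micro F1": self.micro_f1,
                    "Balanced Acc.": self.balanced_accuracy,
                    "Macro Prec.": self.macro_precision,
                    "Micro Prec.": self.micro_precision,
                    "Macro Recall": self.macro_recall,
                    "Micro Recall": self.micro_recall,
                }
            ]
        )


def score_records(
    events: EventMatrix,
    kb: KnowledgeBase,
    classes=None,
    prevalence: dict | None = None,
    residual_weighted: bool = False,
) -> ClassScores:
    """Score every record against every class of the knowledge base.

    The raw score of record r for class c sums, over the rows tied to c,
    the number of the row's feature AVs present in r (optionally weighted by
    each AV's residual against the class). The score used for assignment is
    the matched fraction — raw score divided by the class's total pattern AV
    count (or weight) — so classes with larger pattern sets carry no
    built-in advantage; the fraction is invariant under splitting a row into
    same-class rows. Ties in the argmax break toward the class with the
    highest training prevalence, then the lowest class index.
    """
    if classes is None:
        classes = kb.classes
    classes = tuple(classes)
    if not classes:
        raise ValueError("no classes to score against")
    pos = {c: k for k, c in enumerate(classes)}
    raw = np.zeros((events.n_records, len(classes)))
    denom = np.zeros(len(classes))
    for row in kb.rows:
        if row.class_value is None or row.class_value not in pos:
            continue
        if residual_weighted:
            idx = [fa.av_index for fa in row.feature_avs]
            w = np.array([max(fa.residual_to_class, 0.0) for fa in row.feature_avs])
            contrib = events.indicators[:, idx].astype(float) @ w
            denom[pos[row.class_value]] += w.sum()
        else:
            contrib = coverage_counts(row.feature_avs, events).astype(float)
            denom[pos[row.class_value]] += len(row.feature_avs)
        raw[:, pos[row.class_value]] += contrib
    scores = raw / np.where(denom == 0, 1.0, denom)
    totals = scores.sum(axis=1, keepdims=True)
    probabilities = np.where(totals > 0, scores / np.where(totals == 0, 1, totals), 1.0 / len(classes))
    prev = np.array([0.0 if prevalence is None else prevalence.get(c, 0.0) for c in classes])
    order = sorted(range(len(classes)), key=lambda k: (-prev[k], k))
    reordered = scores[:, order]
    assigned = tuple(classes[order[int(k)]] for k in np.argmax(reordered, axis=1))
    return ClassScores(classes, scores, probabilities, assigned, events.record_ids, raw)


def evaluate_metrics(scores: ClassScores, labels) -> MetricsReport:
    """Macro/micro metrics and balanced accuracy for a scored record set."""
    labels = [str(l) for l in labels]
    if len(labels) != len(scores.record_ids):
        raise ValueError("labels do not align with scored records")
    present = sorted(set(labels))
    if len(present) < 2:
        raise ValueError("need at least 2 classes present in labels")
    missing = [c for c in scores.classes if c not in present]
    if missing:
        warnings.warn(
            f"classes absent from labels excluded from macro averages: {missing}", stacklevel=2
        )
    y_true = np.array(labels)
    y_pred = np.array(scores.assigned)
    mac_p, mac_r, mac_f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="macro", zero_division=0
    )
    mic_p, mic_r, mic_f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="micro", zero_division=0
    )
    onehot = (y_true[:, None] == np.array(present)[None, :]).astype(int)
    cols = [scores.classes.index(c) for c in present]
    proba = scores.probabilities[:, cols]
    macro_auc = roc_auc_score(onehot, proba, average="macro")
    micro_auc = roc_auc_score(onehot, proba, average="micro")
    return MetricsReport(
        float(macro_auc),
        float(micro_auc),
        float(mac_f),
        float(mic_f),
        float(balanced_accuracy_score(y_true, y_pred)),
        float(mac_p),
        float(mic_p),
        float(mac_r),
        float(mic_r),
    )


def class_distribution(labels) -> dict:
    """Per-class percentage of records, reported to 4 decimals."""
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    series = pd.Series([str(l) for l in labels]).value_counts()
    total = float(series.sum())
    return {c: round(100.0 * n / total, 4) for c, n in series.items()}


class PDDClassifier:
    """End-to-end white-box model: discretize → SRM → disentangle → KB → match.

    Parameters mirror the pipeline knobs: ``q`` bins per attribute with a
    dedicated zero bin, residual significance threshold ``tau``, projection
    threshold ``theta``, and the number of retained spaces (None keeps
    components with |eigenvalue| >= 1% of the largest, capped at 10).
    """

    def __init__(
        self,
        q: int = 3,
        zero_bin: bool = True,
        tau: float = DEFAULT_TAU,
        theta: float = 0.0,
        n_spaces: int | None = None,
        residual_weighted: bool = False,
    ):
        self.q = q
        self.zero_bin = zero_bin
        self.tau = tau
        self.theta = theta
        self.n_spaces = n_spaces
        self.residual_weighted = residual_weighted
        self.scheme = None
        self.events_ = None
        self.srm_ = None
        self.spaces_ = None
        self.kb_ = None
        self.classes_ = None
        self.prevalence_ = None

    def fit(self, train: FeatureTable) -> "PDDClassifier":
        if train.labels is None:
            raise ValueError("PDDClassifier.fit requires a labeled table")
        self.scheme = fit_bins(train, q=self.q, zero_bin=self.zero_bin)
        self.events_ = apply_bins(train, self.scheme, attach_labels=True)
        self.srm_ = build_srm(self.events_, tau=self.tau)
        self.spaces_ = build_spaces(self.srm_, n_spaces=self.n_spaces, theta=self.theta)
        self.classes_ = self.events_.label_values
        self.prevalence_ = class_distribution(train.labels)
        self.kb_ = assemble_kb(
            self.spaces_,
            self.events_,
            self.scheme,
            self.srm_,
            provenance={
                "q": self.q,
                "zero_bin": self.zero_bin,
                "tau": self.tau,
                "theta": self.theta,
                "n_spaces": self.n_spaces,
                "n_train_records": train.n_records,
            },
        )
        return self

    def _check_fitted(self):
        if self.kb_ is None:
            raise ValueError("classifier is not fitted")

    def predict_scores(self, table: FeatureTable) -> ClassScores:
        self._check_fitted()
        events = apply_bins(table, self.scheme, attach_labels=False)
        return score_records(
            events,
            self.kb_,
            classes=self.classes_,
            prevalence=self.prevalence_,
            residual_weighted=self.residual_weighted,
        )

    def predict(self, table: FeatureTable) -> tuple:
        return self.predict_scores(table).assigned

    def evaluate(self, table: FeatureTable) -> MetricsReport:
        if table.labels is None:
            raise ValueError("evaluate requires a labeled table")
        return evaluate_metrics(self.predict_scores(table), table.labels)
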