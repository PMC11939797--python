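"""Feature-table I/O, TF-IDF featurization of raw documents, and dataset splitting.

A :class:`FeatureTable` is the package's central container: a records ×
attributes matrix of non-negative reals (e.g. TF-IDF weights or topic
probabilities of clinical notes) with unique record identifiers and an
optional class label (e.g. an ICD-9 code) per record.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.model_selection import train_test_split

__all__ = [
    "FeatureTable",
    "SplitSpec",
    "read_feature_table",
    "write_feature_table",
    "tfidf_featurize",
    "split_dataset",
]


@dataclass(frozen=True)
class FeatureTable:
    """Records × attributes table of non-negative finite reals.

    Parameters
    ----------
    record_ids
        Unique identifier per record (row).
    attribute_names
        Unique name per attribute (column).
    values
        ``(n_records, n_attributes)`` float array; non-negative and finite.
    labels
        Optional class identifier per record.
    """

    record_ids: tuple
    attribute_names: tuple
    values: np.ndarray
    labels: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "record_ids", tuple(str(r) for r in self.record_ids))
        object.__setattr__(self, "attribute_names", tuple(str(a) for a in self.attribute_names))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D records × attributes array")
        object.__setattr__(self, "values", vals)
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        n, f = vals.shape
        if len(self.record_ids) != n:
            raise ValueError("record_ids length does not match number of rows")
        if len(self.attribute_names) != f:
            raise ValueError("attribute_names length does not match number of columns")
        if len(set(self.record_ids)) != n:
            raise ValueError("record_ids must be unique")
        if len(set(self.attribute_names)) != f:
            raise ValueError("attribute_names must be unique")
        if not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at record {self.record_ids[i]!r}, attribute {self.attribute_names[j]!r}"
            )
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative value {vals[i, j]!r} at record {self.record_ids[i]!r}, "
                f"attribute {self.attribute_names[j]!r}"
            )
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match number of records")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def subset(self, indices) -> "FeatureTable":
        """Row subset preserving order of ``indices``."""
        indices = np.asarray(indices, dtype=int)
        labels = None if self.labels is None else tuple(self.labels[i] for i in indices)
        return FeatureTable(
            tuple(self.record_ids[i] for i in indices),
            self.attribute_names,
            self.values[indices],
            labels,
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.record_ids), columns=list(self.attribute_names))
        df.index.name = "record_id"
        if self.labels is not None:
            df[label_column] = list(self.labels)
        return df


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test proportions plus the seed that fixes the partition."""

    train_fraction: float = 0.70
    valid_fraction: float = 0.10
    test_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self):
        for f in (self.train_fraction, self.valid_fraction, self.test_fraction):
            if not (0.0 < f < 1.0):
                raise ValueError("split fractions must lie in (0, 1)")
        if abs(self.train_fraction + self.valid_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def read_feature_table(path, label_column: str | None = None) -> FeatureTable:
    """Read a CSV feature table (first column record id, optional label column).

    Raises ``ValueError`` naming the offending cell for negative or
    non-numeric entries and for duplicate record ids.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("feature table needs a record-id column and at least one attribute")
    record_ids = df.iloc[:, 0].astype(str).tolist()
    dupes = pd.Series(record_ids)[pd.Series(record_ids).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate record id {dupes.iloc[0]!r}")
    labels = None
    feature_cols = list(df.columns[1:])
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        labels = df[label_column].astype(str).tolist()
        feature_cols.remove(label_column)
    values = np.empty((len(df), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        for i, cell in enumerate(df[col]):
            try:
                v = float(cell)  # exact round trip, unlike the fast CSV float parser
            except (TypeError, ValueError):
                v = float("nan")
            if not np.isfinite(v):
                raise ValueError(
                    f"non-numeric value {cell!r} at record {record_ids[i]!r}, column {col!r}"
                )
            if v < 0:
                raise ValueError(
                    f"negative value {v!r} at record {record_ids[i]!r}, column {col!r}"
                )
            values[i, j] = v
    return FeatureTable(tuple(record_ids), tuple(feature_cols), values, None if labels is None else tuple(labels))


def write_feature_table(table: FeatureTable, path, label_column: str = "label") -> None:
    """Write the CSV dialect read by :func:`read_feature_table`.

    Values are printed with 17 significant digits so a round trip is exact.
    """
    table.to_frame(label_column).to_csv(path, float_format="%.17g")


def _tokenizer_pattern() -> str:
    # single-character tokens are kept (the sklearn default drops them)
    return r"(?u)\b\w+\b"


def tfidf_featurize(documents, vocabulary_size: int = 250, ngram_max: int = 1) -> FeatureTable:
    """TF-IDF featurize raw documents into a :class:`FeatureTable`.

    The vocabulary is the ``vocabulary_size`` n-grams (up to ``ngram_max``)
    with the highest document frequency, ties broken lexicographically.
    Weights are raw term count × smoothed idf, ``idf = ln((1+N)/(1+df)) + 1``,
    and each row is L2-normalized (all-zero rows are left as zeros).
    """
    documents = list(documents)
    if len(documents) < 2:
        raise ValueError("need at least 2 documents")
    if vocabulary_size < 1:
        raise ValueError("vocabulary_size must be >= 1")
    if ngram_max not in (1, 2):
        raise ValueError("ngram_max must be 1 or 2")
    cv = CountVectorizer(ngram_range=(1, ngram_max), token_pattern=_tokenizer_pattern(), lowercase=True)
    try:
        counts = cv.fit_transform(documents)
    except ValueError as exc:  # empty vocabulary
        raise ValueError("corpus contains no tokens") from exc
    terms = cv.get_feature_names_out()
    df_counts = np.asarray((counts > 0).sum(axis=0)).ravel()
    order = sorted(range(len(terms)), key=lambda i: (-df_counts[i], terms[i]))
    if vocabulary_size > len(terms):
        warnings.warn(
            f"vocabulary_size={vocabulary_size} exceeds the {len(terms)} available terms; using all",
            stacklevel=2,
        )
        vocabulary_size = len(terms)
    sel = order[:vocabulary_size]
    n_docs = len(documents)
    idf = np.log((1.0 + n_docs) / (1.0 + df_counts[sel])) + 1.0
    tf = counts[:, sel].toarray().astype(float)
    weights = tf * idf
    norms = np.linalg.norm(weights, axis=1)
    nonzero = norms > 0
    weights[nonzero] /= norms[nonzero, None]
    record_ids = tuple(f"d{i}" for i in range(n_docs))
    return FeatureTable(record_ids, tuple(terms[sel]), weights)


def split_dataset(table: FeatureTable, spec: SplitSpec):
    """Stratified train/validation/test split, deterministic given the seed.

    Falls back to an unstratified split (with a warning) when a class is too
    small to stratify.
    """
    if table.labels is None:
        raise ValueError("split_dataset requires a labeled table")
    labels = np.asarray(table.labels)
    _, counts = np.unique(labels, return_counts=True)
    stratify = labels
    if counts.min() < 3:
        warnings.warn("a class has fewer than 3 records; falling back to unstratified split", stacklevel=2)
        stratify = None
    idx = np.arange(table.n_records)
    n = table.n_records
    n_test = max(1, round(n * spec.test_fraction))  # integer counts avoid float-fraction drift
    n_valid = max(1, round(n * spec.valid_fraction))
    rest, test = train_test_split(
        idx,
        test_size=n_test,
        random_state=spec.seed,
        stratify=stratify,
    )
    train, valid = train_test_split(
        rest,
        test_size=n_valid,
        random_state=spec.seed + 1,
        stratify=None if stratify is None else labels[rest],
    )
    return table.subset(np.sort(train)), table.subset(np.sort(valid)), table.subset(np.sort(test))
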