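"""Discretization of numerical features into event-based attribute values (AVs).

Each attribute is cut into Q bins; with the zero bin enabled, exact zeros
form their own event and quantile cut points are computed over strictly
positive values only — the natural treatment for zero-inflated TF-IDF or
topic-probability tables, where "the term is absent" is itself an event.
Class labels can be attached as AVs of a designated label attribute so that
label–feature associations are analyzed on the same footing as
feature–feature ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .io_features import FeatureTable

__all__ = [
    "AttributeBins",
    "BinningScheme",
    "AV",
    "EventMatrix",
    "fit_bins",
    "apply_bins",
    "LABEL_ATTRIBUTE",
]

LABEL_ATTRIBUTE = "__class__"


@dataclass(frozen=True)
class AttributeBins:
    """Interior cut points for one attribute (over positives when zero-binned)."""

    cuts: tuple  # strictly increasing interior cut points
    has_positive: bool  # False for an all-zero attribute under zero-binning
    vmin: float
    vmax: float

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cuts)
        object.__setattr__(self, "cuts", cuts)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cut points must be strictly increasing")


@dataclass(frozen=True)
class BinningScheme:
    attributes: tuple
    bins: dict  # attribute -> AttributeBins
    q: int
    zero_bin: bool
    percent_style: bool  # render ranges as percentages (probability-like tables)

    def n_bins(self, attribute: str) -> int:
        b = self.bins[attribute]
        pos = (len(b.cuts) + 1) if b.has_positive else 0
        return (1 if self.zero_bin else 0) + max(pos, 0 if self.zero_bin else 1)

    def _fmt(self, v: float) -> str:
        if self.percent_style:
            return f"{100.0 * v:.4g}%"
        return f"{v:.4g}"

    def range_label(self, attribute: str, bin_index: int) -> str:
        """Human-readable value range of one bin."""
        b = self.bins[attribute]
        if self.zero_bin:
            if bin_index == 0:
                return f"={self._fmt(0.0)}"
            edges = (0.0,) + b.cuts + (b.vmax,)
            lo, hi = edges[bin_index - 1], edges[bin_index]
            return f"({self._fmt(lo)}, {self._fmt(hi)}]"
        edges = (b.vmin,) + b.cuts + (b.vmax,)
        lo, hi = edges[bin_index], edges[bin_index + 1]
        bracket = "[" if bin_index == 0 else "("
        return f"{bracket}{self._fmt(lo)}, {self._fmt(hi)}]"

    def to_yaml(self, path) -> None:
        payload = {
            "q": self.q,
            "zero_bin": self.zero_bin,
            "percent_style": self.percent_style,
            "attributes": {
                a: {
                    "cuts": [float(c) for c in self.bins[a].cuts],
                    "has_positive": self.bins[a].has_positive,
                    "vmin": float(self.bins[a].vmin),
                    "vmax": float(self.bins[a].vmax),
                }
                for a in self.attributes
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BinningScheme":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        bins = {
            a: AttributeBins(
                tuple(spec["cuts"]), spec["has_positive"], spec["vmin"], spec["vmax"]
            )
            for a, spec in payload["attributes"].items()
        }
        return cls(
            tuple(payload["attributes"]), bins, payload["q"], payload["zero_bin"], payload["percent_style"]
        )


@dataclass(frozen=True)
class AV:
    """One attribute value: a discretized event of a feature, or a class label."""

    attribute: str
    bin_index: int
    range_label: str
    is_label: bool = False
    label_value: str | None = None

    @property
    def name(self) -> str:
        if self.is_label:
            return f"class={self.label_value}"
        return f"{self.attribute}∈{self.range_label}"


@dataclass(frozen=True)
class EventMatrix:
    """Records × AVs one-hot indicators (one AV per attribute per record)."""

    indicators: np.ndarray  # (n_records, n_avs) int8
    av_catalog: tuple  # of AV
    attr_codes: np.ndarray  # (n_avs,) attribute index per AV; label attr = n_attributes
    record_ids: tuple
    attributes: tuple
    labels: tuple | None = None
    label_values: tuple = ()

    @property
    def n_records(self) -> int:
        return self.indicators.shape[0]

    @property
    def n_avs(self) -> int:
        return self.indicators.shape[1]

    def av_names(self):
        return [av.name for av in self.av_catalog]

    def label_av_indices(self) -> np.ndarray:
        return np.array([i for i, av in enumerate(self.av_catalog) if av.is_label], dtype=int)


def fit_bins(table: FeatureTable, q: int = 3, zero_bin: bool = True) -> BinningScheme:
    """Fit per-attribute quantile bins.

    With ``zero_bin`` set, exact zeros form their own event and the ``q``
    quantile bins are fitted over strictly positive values; attributes with
    fewer than ``q`` distinct (positive) values collapse to distinct-value
    bins; constant attributes get a single bin.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if table.n_records == 0:
        raise ValueError("cannot fit bins on an empty table")
    bins = {}
    for j, attr in enumerate(table.attribute_names):
        col = table.values[:, j]
        domain = col[col > 0] if zero_bin else col
        if domain.size == 0:
            bins[attr] = AttributeBins((), False, 0.0, 0.0)
            continue
        distinct = np.unique(domain)
        if distinct.size == 1:
            cuts = ()
        elif distinct.size < q:
            warnings.warn(
                f"attribute {attr!r}: q={q} exceeds {distinct.size} distinct values; "
                "collapsing to distinct-value bins",
                stacklevel=2,
            )
            cuts = tuple(distinct[:-1])
        else:
            qs = np.arange(1, q) / q
            cand = np.unique(np.quantile(domain, qs))
            cuts = tuple(c for c in cand if distinct[0] <= c < distinct[-1])
        bins[attr] = AttributeBins(cuts, True, float(col.min()), float(col.max()))
    percent_style = bool(table.values.size and table.values.max() <= 1.0)
    return BinningScheme(table.attribute_names, bins, q, zero_bin, percent_style)


def apply_bins(
    table: FeatureTable,
    scheme: BinningScheme,
    attach_labels: bool = False,
    label_values=None,
) -> EventMatrix:
    """One-hot encode a table against a fitted binning scheme.

    Values outside the fitted range clamp to the outermost bin. With
    ``attach_labels``, each distinct class becomes an AV of the designated
    label attribute; an unseen label raises (labels define the class space).
    """
    if tuple(scheme.attributes) != tuple(table.attribute_names):
        raise ValueError("scheme attributes do not match table attributes")
    catalog: list[AV] = []
    attr_codes: list[int] = []
    columns: list[np.ndarray] = []
    for j, attr in enumerate(table.attribute_names):
        b = scheme.bins[attr]
        col = table.values[:, j]
        cuts = np.asarray(b.cuts)
        if scheme.zero_bin:
            if b.has_positive:
                assignment = np.where(col == 0.0, 0, np.searchsorted(cuts, col, side="left") + 1)
                n_bins = len(cuts) + 2
            else:
                assignment = np.zeros(col.shape, dtype=int)  # clamp: only the zero bin exists
                n_bins = 1
        else:
            assignment = np.searchsorted(cuts, col, side="left")
            n_bins = len(cuts) + 1
        for k in range(n_bins):
            catalog.append(AV(attr, k, scheme.range_label(attr, k)))
            attr_codes.append(j)
        onehot = np.zeros((table.n_records, n_bins), dtype=np.int8)
        onehot[np.arange(table.n_records), assignment] = 1
        columns.append(onehot)
    lvals: tuple = ()
    if attach_labels:
        if table.labels is None:
            raise ValueError("attach_labels requires a labeled table")
        lvals = tuple(sorted(set(table.labels))) if label_values is None else tuple(label_values)
        unseen = set(table.labels) - set(lvals)
        if unseen:
            raise ValueError(f"unseen label(s) {sorted(unseen)} not in the known class space")
        pos = {v: k for k, v in enumerate(lvals)}
        onehot = np.zeros((table.n_records, len(lvals)), dtype=np.int8)
        for i, lab in enumerate(table.labels):
            onehot[i, pos[lab]] = 1
        for k, v in enumerate(lvals):
            catalog.append(AV(LABEL_ATTRIBUTE, k, v, is_label=True, label_value=v))
            attr_codes.append(table.n_attributes)
        columns.append(onehot)
    return EventMatrix(
        np.hstack(columns),
        tuple(catalog),
        np.asarray(attr_codes, dtype=int),
        table.record_ids,
        table.attribute_names,
        table.labels,
        lvals,
    )
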