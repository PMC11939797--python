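"""Assembly and export of the three-section knowledge base.

The output grid has a Knowledge Section (DSU addresses), a Pattern Section
(significant AV associations with readable value ranges and residuals
against the row's class), and a Data Section (how often each record matches
the row's pattern, i.e. how many of the row's feature AVs the record
possesses).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretize import BinningScheme, EventMatrix
from .disentangle import DSUAddress
from .srm import ResidualMatrix

__all__ = ["FeatureAV", "PatternRow", "KnowledgeBase", "assemble_kb", "coverage_counts", "export_kb"]


@dataclass(frozen=True)
class FeatureAV:
    av_index: int
    attribute: str
    range_label: str
    residual_to_class: float  # d against the row's class AV; NaN for unlabeled rows

    @property
    def name(self) -> str:
        return f"{self.attribute}∈{self.range_label}"


@dataclass(frozen=True)
class PatternRow:
    """One knowledge-base row: a DSU-addressed pattern tied to one class AV."""

    dsu: DSUAddress
    class_value: str | None  # None for an unlabeled pattern
    class_av: int | None
    feature_avs: tuple  # of FeatureAV, non-empty
    coverage: np.ndarray  # per-record matched-AV counts

    def __post_init__(self):
        if not self.feature_avs:
            raise ValueError("a pattern row needs at least one feature AV")


@dataclass(frozen=True)
class KnowledgeBase:
    rows: tuple  # of PatternRow
    av_catalog: tuple
    record_ids: tuple
    provenance: dict = field(default_factory=dict)

    @property
    def classes(self) -> tuple:
        return tuple(sorted({r.class_value for r in self.rows if r.class_value is not None}))


def coverage_counts(feature_av_indices, events: EventMatrix) -> np.ndarray:
    """Per-record count of the row's feature AVs that the record possesses."""
    idx = [fa.av_index if isinstance(fa, FeatureAV) else int(fa) for fa in feature_av_indices]
    if any(i >= events.n_avs for i in idx):
        raise ValueError("feature AV outside the event-matrix catalog")
    return events.indicators[:, idx].astype(np.int64).sum(axis=1)


def assemble_kb(
    spaces,
    events: EventMatrix,
    scheme: BinningScheme,
    srm: ResidualMatrix,
    provenance: dict | None = None,
) -> KnowledgeBase:
    """Build one row per (subgroup × class AV in the subgroup).

    A class row's Pattern Section lists the subgroup AVs that are
    significantly associated with that class AV (d > tau) — the subgroup may
    also contain AVs tied to other classes of the same cluster, which belong
    to their own rows. Subgroups without a class AV yield a single unlabeled
    row carrying all their AVs; subgroups containing only class AVs yield
    none (a pattern needs feature AVs).
    """
    if srm.av_catalog != events.av_catalog:
        raise ValueError("events and SRM were built from different AV catalogs")
    catalog = events.av_catalog
    rows = []
    for space in spaces:
        for g in (1, 2):
            for u, subgroup in enumerate(space.subgroups[g], start=1):
                class_avs = sorted(a for a in subgroup if catalog[a].is_label)
                feat_idx = [a for a in subgroup if not catalog[a].is_label]
                if not feat_idx:
                    continue
                dsu = DSUAddress(space.index, g, u)
                if class_avs:
                    for cav in class_avs:
                        assoc = [a for a in feat_idx if srm.d[a, cav] > srm.tau]
                        if not assoc:
                            continue
                        feats = tuple(
                            FeatureAV(a, catalog[a].attribute, catalog[a].range_label, float(srm.d[a, cav]))
                            for a in assoc
                        )
                        cov = coverage_counts(assoc, events)
                        rows.append(PatternRow(dsu, catalog[cav].label_value, cav, feats, cov))
                else:
                    cov = coverage_counts(feat_idx, events)
                    feats = tuple(
                        FeatureAV(a, catalog[a].attribute, catalog[a].range_label, float("nan"))
                        for a in feat_idx
                    )
                    rows.append(PatternRow(dsu, None, None, feats, cov))
    seen = set()
    for r in rows:
        key = (r.dsu.space, r.dsu.group, r.dsu.subgroup, r.class_value)
        if key in seen:
            raise ValueError(f"duplicate knowledge-base row {key}")
        seen.add(key)
    return KnowledgeBase(tuple(rows), catalog, events.record_ids, dict(provenance or {}))


def kb_to_frame(kb: KnowledgeBase) -> pd.DataFrame:
    """Grid layout: Knowledge Section, then one column per feature AV, then records."""
    av_union = sorted({fa.av_index for row in kb.rows for fa in row.feature_avs})
    av_headers = {a: kb.av_catalog[a].name for a in av_union}
    records = list(kb.record_ids)
    data = []
    for row in kb.rows:
        cells = {
            "space": row.dsu.space,
            "group": row.dsu.group,
            "subgroup": row.dsu.subgroup,
            "class": "" if row.class_value is None else row.class_value,
        }
        present = {fa.av_index: fa for fa in row.feature_avs}
        for a in av_union:
            if a in present:
                d = present[a].residual_to_class
                cells[av_headers[a]] = "x" if np.isnan(d) else f"d={d:.3f}"
            else:
                cells[av_headers[a]] = ""
        for rid, c in zip(records, row.coverage):
            cells[rid] = int(c)
        data.append(cells)
    columns = ["space", "group", "subgroup", "class"] + [av_headers[a] for a in av_union] + records
    return pd.DataFrame(data, columns=columns)


def export_kb(kb: KnowledgeBase, path) -> None:
    """Write the knowledge-base CSV with a provenance header comment line."""
    frame = kb_to_frame(kb)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# provenance: " + json.dumps(kb.provenance, sort_keys=True) + "\n")
        frame.to_csv(fh, index=False)
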