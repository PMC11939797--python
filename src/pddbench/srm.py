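"""Statistical residual matrix (SRM) of adjusted standardized residuals.

For two attribute values a and b with co-occurrence count o, marginal counts
n_a and n_b out of n records, the adjusted standardized residual is

    e = n_a * n_b / n
    z = (o - e) / sqrt(e)
    v = (1 - n_a/n) * (1 - n_b/n)
    d = z / sqrt(v)

which is approximately standard normal when a and b are independent, so a
threshold such as |d| > 1.96 flags associations at the usual 5% level.
Pairs of AVs belonging to the same attribute are structurally exclusive and
set to 0 by construction, as is the diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretize import EventMatrix

__all__ = ["ResidualMatrix", "adjusted_residual", "build_srm", "significant_pairs"]

DEFAULT_TAU = 1.96


@dataclass(frozen=True)
class ResidualMatrix:
    """Symmetric AV × AV matrix of adjusted residuals with marginals."""

    d: np.ndarray  # (n_avs, n_avs) float
    counts: np.ndarray  # (n_avs,) AV support counts
    n_records: int
    tau: float
    av_catalog: tuple
    attr_codes: np.ndarray

    @property
    def n_avs(self) -> int:
        return self.d.shape[0]

    def to_frame(self) -> pd.DataFrame:
        names = [av.name for av in self.av_catalog]
        return pd.DataFrame(self.d, index=names, columns=names)

    def export_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def adjusted_residual(o: float, n_a: float, n_b: float, n: float) -> float:
    """Adjusted standardized residual d for one AV pair.

    Returns 0 when the expected count or the variance factor vanishes
    (defined non-informative).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= o <= min(n_a, n_b) <= n):
        raise ValueError(f"count bounds violated: o={o}, n_a={n_a}, n_b={n_b}, n={n}")
    e = n_a * n_b / n
    if e == 0:
        return 0.0
    v = (1.0 - n_a / n) * (1.0 - n_b / n)
    if v <= 0:
        return 0.0
    z = (o - e) / math.sqrt(e)
    return z / math.sqrt(v)


def build_srm(events: EventMatrix, tau: float = DEFAULT_TAU) -> ResidualMatrix:
    """Adjusted residuals for every AV pair from distinct attributes.

    Same-attribute pairs and the diagonal are forced to 0; the result is
    symmetric and finite everywhere.
    """
    if events.n_records == 0:
        raise ValueError("cannot build an SRM from an empty event matrix")
    ind = events.indicators.astype(np.int64)
    n = events.n_records
    o = ind.T @ ind
    counts = np.diag(o).astype(float)
    e = np.outer(counts, counts) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(e > 0, (o - e) / np.sqrt(e), 0.0)
        v = np.outer(1.0 - counts / n, 1.0 - counts / n)
        d = np.where(v > 0, z / np.sqrt(np.clip(v, 1e-300, None)), 0.0)
    same_attr = events.attr_codes[:, None] == events.attr_codes[None, :]
    d[same_attr] = 0.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against floating-point noise
    return ResidualMatrix(d, counts, n, float(tau), events.av_catalog, events.attr_codes)


def significant_pairs(srm: ResidualMatrix) -> np.ndarray:
    """Boolean adjacency over AVs: edge iff d(a, b) > tau.

    Only positive residuals create edges — patterns are co-occurrences;
    negative associations stay in the matrix for disentanglement and
    contrast display but do not link AVs.
    """
    adj = srm.d > srm.tau
    return adj & adj.T
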