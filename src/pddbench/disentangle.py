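"""Disentanglement: PCA of the SRM into spaces, groups, and AV subgroups.

The symmetric SRM is eigendecomposed; each retained principal component is
one *disentangled space*. Within a space, AVs split into two contrasting
groups by the sign of their projection. Each group is further divided into
*AV subgroups*: maximal subsets in which every AV is significantly
associated with at least one other member and with no AV outside the
subset — exactly the connected components of the significant-association
graph restricted to the group. A subgroup address [space, group, subgroup]
is a Disentangled Space Unit (DSU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .srm import ResidualMatrix, significant_pairs

__all__ = [
    "DSUAddress",
    "DisentangledSpace",
    "principal_projections",
    "form_groups",
    "form_subgroups",
    "build_spaces",
]

MAX_SPACES = 10
EIGENVALUE_FRACTION = 0.01


@dataclass(frozen=True)
class DSUAddress:
    """1-based address of one pattern: (space, group, subgroup)."""

    space: int
    group: int
    subgroup: int

    def __post_init__(self):
        if self.space < 1 or self.subgroup < 1 or self.group not in (1, 2):
            raise ValueError(f"invalid DSU address {(self.space, self.group, self.subgroup)}")

    def __str__(self) -> str:
        return f"DSU[{self.space},{self.group},{self.subgroup}]"


@dataclass(frozen=True)
class DisentangledSpace:
    """One principal component of the SRM with its groups and subgroups."""

    index: int  # 1-based component rank by |eigenvalue|
    eigenvalue: float
    projections: np.ndarray  # per-AV projection on this component
    groups: dict  # g in {1, 2} -> np.ndarray of AV indices
    subgroups: dict  # g -> list of lists of AV indices


def principal_projections(srm: ResidualMatrix, n_spaces: int | None = None):
    """Eigendecompose the SRM and project AVs onto principal components.

    Components are ordered by descending |eigenvalue|; the projection of AV
    a on component c is ``eigvec_c[a] * sqrt(|eigval_c|)``. Each eigenvector
    is scaled so its largest-magnitude entry is positive, making group
    numbering stable across runs and platforms.

    Returns ``(eigenvalues, projections)`` with ``projections`` of shape
    ``(n_components, n_avs)``.
    """
    eigvals, eigvecs = np.linalg.eigh(srm.d)
    order = np.argsort(-np.abs(eigvals), kind="stable")
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = np.abs(eigvals).max() if eigvals.size else 0.0
    rank = int(np.sum(np.abs(eigvals) > max(scale, 1.0) * 1e-12))
    if n_spaces is None:
        keep = int(np.sum(np.abs(eigvals) >= EIGENVALUE_FRACTION * scale)) if scale > 0 else 0
        keep = min(keep, MAX_SPACES, rank)
    else:
        if n_spaces < 1:
            raise ValueError("n_spaces must be >= 1")
        if n_spaces > rank:
            warnings.warn(
                f"n_spaces={n_spaces} exceeds SRM rank {rank}; truncating", stacklevel=2
            )
        keep = min(n_spaces, rank)
    projections = np.empty((keep, srm.n_avs))
    for c in range(keep):
        vec = eigvecs[:, c].copy()
        i = int(np.argmax(np.abs(vec)))
        if vec[i] < 0:
            vec = -vec
        projections[c] = vec * np.sqrt(abs(eigvals[c]))
    return eigvals[:keep], projections


def form_groups(projections: np.ndarray, theta: float = 0.0):
    """Split one component's projections into two contrasting groups.

    Group 1: projection > theta; group 2: projection < -theta; AVs within
    [-theta, theta] stay unassigned for this space.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return {
        1: np.flatnonzero(projections > theta),
        2: np.flatnonzero(projections < -theta),
    }


def form_subgroups(group: np.ndarray, adjacency: np.ndarray) -> list:
    """Connected components of the association graph restricted to the group.

    Singleton AVs with no in-group edge are dropped (no association, no
    pattern). Subgroups are ordered by descending size, ties by smallest
    member AV index.
    """
    group = np.asarray(group, dtype=int)
    if group.size == 0:
        return []
    sub = adjacency[np.ix_(group, group)]
    n_comp, labels = connected_components(csr_matrix(sub), directed=False)
    comps = []
    for c in range(n_comp):
        members = group[labels == c]
        if members.size == 1 and not sub[labels == c][:, labels == c].any():
            continue  # isolated AV: not associated with anything in the group
        comps.append(sorted(int(m) for m in members))
    comps.sort(key=lambda ms: (-len(ms), ms[0]))
    return comps


def build_spaces(
    srm: ResidualMatrix,
    n_spaces: int | None = None,
    theta: float = 0.0,
    adjacency: np.ndarray | None = None,
) -> list:
    """Full disentanglement: projections → groups → subgroups per component.

    Spaces in which neither group yields a subgroup are omitted; the space
    index keeps the component's rank so DSU addresses stay meaningful.
    """
    if adjacency is None:
        adjacency = significant_pairs(srm)
    eigvals, projections = principal_projections(srm, n_spaces)
    spaces = []
    for c in range(projections.shape[0]):
        groups = form_groups(projections[c], theta)
        subgroups = {g: form_subgroups(groups[g], adjacency) for g in (1, 2)}
        if not subgroups[1] and not subgroups[2]:
            continue
        spaces.append(
            DisentangledSpace(c + 1, float(eigvals[c]), projections[c], groups, subgroups)
        )
    return spaces
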