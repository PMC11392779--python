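"""Weighted Gower dissimilarity and the UPGMA functional dendrogram.

Functional diversity (FD) and endemism (FE) reuse the branch-length engine
on a dendrogram built from species traits: mixed-type traits are compared
with the weighted Gower similarity coefficient, converted to dissimilarity
D = 1 − S, and clustered by UPGMA (unweighted pair-group average linkage).
The dendrogram's node heights are half the merging average dissimilarity, so
cophenetic distances of an exactly ultrametric D are reproduced exactly.

Gower similarity between species i and j over traits k:

    S_ij = Σ_k w_k δ_ijk s_ijk / Σ_k w_k δ_ijk

with δ_ijk = 1 iff trait k is non-missing for both species; s_ijk is
1[equal] for binary/categorical traits and 1 − |x_ik − x_jk|/range_k for
continuous traits; ordinal traits are rank-scaled first and then treated as
continuous (Gower's rank-normalized distance).  Trait ranges are taken over
the full species pool so one global dendrogram describes all cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import IncomparablePairError
from .trees import BranchTable, RootedTree, TreeNode

__all__ = [
    "TraitMatrix",
    "weighted_gower_similarity",
    "gower_dissimilarity",
    "upgma",
    "fd_fe_surfaces",
]

TRAIT_TYPES = ("binary", "ordinal", "continuous", "categorical")


@dataclass
class TraitMatrix:
    """Species × trait values with per-trait type and weight.

    ``values`` is a DataFrame indexed by species id; missing entries are
    NaN.  ``types`` maps trait name → one of binary/ordinal/continuous/
    categorical; ``weights`` maps trait name → weight in [0, 1].
    """

    values: pd.DataFrame
    types: dict[str, str]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait in self.values.columns:
            t = self.types.get(trait)
            if t not in TRAIT_TYPES:
                raise ValueError(f"trait {trait!r} has invalid type {t!r}")
            w = self.weights.setdefault(trait, 1.0)
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"weight for {trait!r} must be in [0, 1]")
        if all(w == 0 for w in self.weights.values()):
            raise ValueError("trait weights must not all be zero")

    @property
    def species(self) -> list[str]:
        return list(self.values.index)


def weighted_gower_similarity(traits: TraitMatrix) -> pd.DataFrame:
    """Weighted Gower similarity matrix S over all species pairs."""
    species = traits.species
    n = len(species)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for trait in traits.values.columns:
        w = traits.weights[trait]
        if w == 0:
            continue
        kind = traits.types[trait]
        col = traits.values[trait]
        if kind in ("binary", "categorical"):
            vals = col.to_numpy(object)
            present = ~pd.isna(col).to_numpy()
            s = (vals[:, None] == vals[None, :]).astype(float)
        else:
            x = col.to_numpy(float)
            present = np.isfinite(x)
            if kind == "ordinal":
                ranked = np.full_like(x, np.nan)
                ranked[present] = rankdata(x[present])
                x = ranked
            rng = np.nanmax(x) - np.nanmin(x) if present.any() else 0.0
            if rng == 0:
                s = np.ones((n, n))
            else:
                s = 1.0 - np.abs(x[:, None] - x[None, :]) / rng
        delta = present[:, None] & present[None, :]
        num += np.where(delta, w * np.nan_to_num(s), 0.0)
        den += np.where(delta, w, 0.0)
    if np.any(den == 0):
        i, j = np.argwhere(den == 0)[0]
        raise IncomparablePairError(
            f"species pair ({species[i]!r}, {species[j]!r}) shares no "
            "non-missing weighted trait"
        )
    S = num / den
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=species, columns=species)


def gower_dissimilarity(traits: TraitMatrix) -> pd.DataFrame:
    """Gower dissimilarity D = 1 − S."""
    return 1.0 - weighted_gower_similarity(traits)


def upgma(D: pd.DataFrame) -> RootedTree:
    """UPGMA dendrogram from a symmetric dissimilarity matrix.

    Average-linkage agglomeration; node heights are half the merging average
    dissimilarity so the cophenetic distance between two leaves equals the
    average dissimilarity of the clusters merged at their join.  Ties are
    broken by the lexicographically smallest pair of cluster representatives
    (the minimum species label in each cluster) for cross-platform
    reproducibility.
    """
    labels = list(D.index)
    M = np.asarray(D, dtype=float).copy()
    if M.shape[0] != M.shape[1] or list(D.columns) != labels:
        raise ValueError("D must be square with matching index and columns")
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("D must be symmetric")
    if np.any(M < -1e-12):
        raise ValueError("D must be non-negative")
    np.fill_diagonal(M, np.inf)

    n = len(labels)
    if n == 1:
        return RootedTree(TreeNode(label=labels[0]))
    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    reps = {i: labels[i] for i in range(n)}
    active = set(range(n))

    while len(active) > 1:
        act = sorted(active)
        sub = M[np.ix_(act, act)]
        dmin = sub.min()
        # all index pairs attaining the minimum, tie-broken lexicographically
        best: tuple[str, str] | None = None
        best_pair = (act[0], act[0])
        ii, jj = np.where(sub <= dmin * (1 + 1e-15) + 0.0)
        for a, b in zip(ii, jj):
            if a >= b or sub[a, b] > dmin:
                continue
            i, j = act[a], act[b]
            key = tuple(sorted((reps[i], reps[j])))
            if best is None or key < best:
                best, best_pair = key, (i, j)
        i, j = best_pair
        h = dmin / 2.0
        parent = TreeNode()
        for k in (i, j):
            child = nodes[k]
            child.length = h - heights[k]
            parent.add_child(child)
        new = max(nodes) + 1
        nodes[new] = parent
        sizes[new] = sizes[i] + sizes[j]
        heights[new] = h
        reps[new] = min(reps[i], reps[j])
        # grow M with the average-linkage row for the merged cluster
        M = np.pad(M, ((0, 1), (0, 1)), constant_values=np.inf)
        for k in active:
            if k in (i, j):
                continue
            d = (sizes[i] * M[i, k] + sizes[j] * M[j, k]) / (
                sizes[i] + sizes[j]
            )
            M[new, k] = M[k, new] = d
        active.discard(i)
        active.discard(j)
        active.add(new)

    root = nodes[active.pop()]
    return RootedTree(root)


def fd_fe_surfaces(
    dendrogram: RootedTree,
    presence: np.ndarray,
    species: list[str],
    mode: str = "root",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell FD and FE: branch-sum diversity and range-weighted endemism
    evaluated on the functional dendrogram. NaN for empty cells."""
    table = BranchTable(dendrogram, presence, species)
    return table.pd_per_cell(mode=mode), table.endemism_per_cell(mode=mode)
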