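"""Hierarchical clustering of Δψ change profiles.

Builds the (changed events) × (cell lines) matrix of representative Δψ
values — the mean of the two per-siRNA shifts — and clusters rows and
columns agglomeratively with Euclidean distance and either average or
classic Ward ("ward.D") linkage.  With sign-coherent knockdown responses a
two-cluster cut separates events shifting toward exon inclusion from those
shifting toward exclusion.

ward.D semantics: the Lance–Williams Ward update applied to *unsquared*
Euclidean input distances (the historical hclust convention), as opposed to
ward.D2 which squares them.  Implemented by handing sqrt-transformed
distances to scipy's Ward recursion and squaring the resulting heights,
which is algebraically the ward.D recursion on the original distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "DpsiMatrix",
    "ClusterTree",
    "build_dpsi_matrix",
    "hierarchical_cluster",
    "cut_k",
]

LINKAGES = ("average", "ward")


@dataclass
class DpsiMatrix:
    """Representative Δψ per (changed event, cell line).

    ``values``: DataFrame indexed by ase_id with one column per cell line;
    entries are mean(Δψ_siRNA1, Δψ_siRNA2) or NaN where not evaluable.
    Rows are restricted to events called changed in at least one line.
    ``genes`` maps ase_id → gene symbol for row labelling.
    """

    values: pd.DataFrame
    genes: pd.Series

    @property
    def row_labels(self) -> list[str]:
        return [f"{self.genes.get(a, a)}|{a}" for a in self.values.index]


def build_dpsi_matrix(
    calls: pd.DataFrame,
    genes: Optional[Mapping[str, str]] = None,
    threshold: float = 8.0,
) -> DpsiMatrix:
    """Assemble the change-profile matrix from a change-call table.

    ``calls`` follows the psi-module call schema (ase_id, cell_line,
    changed, dpsi1, dpsi2, ...).  The representative entry is the mean of
    the two per-siRNA Δψ; a pair with either value missing yields NaN.
    Raises if no event is changed anywhere.
    """
    changed_ases = calls.loc[calls["changed"], "ase_id"].unique()
    if changed_ases.size == 0:
        raise ValueError("no changed events: Δψ matrix would be empty")
    sub = calls[calls["ase_id"].isin(changed_ases)].copy()
    sub["dpsi_mean"] = (sub["dpsi1"] + sub["dpsi2"]) / 2.0
    values = sub.pivot_table(
        index="ase_id", columns="cell_line", values="dpsi_mean", aggfunc="first", dropna=False
    )
    values = values.loc[sorted(changed_ases)]
    values.columns.name = None
    gene_map = pd.Series({a: (genes or {}).get(a, a) for a in values.index}, name="gene")
    return DpsiMatrix(values=values, genes=gene_map)


@dataclass
class ClusterTree:
    """Agglomerative dendrogram over one axis of a Δψ matrix.

    ``merges`` is a scipy-style linkage matrix whose height column is in
    the semantics of the requested linkage (for ward, classic ward.D
    heights).  Heights are non-decreasing along the merge sequence for both
    implemented linkages.
    """

    merges: np.ndarray
    labels: list[str]
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self._scipy_merges())]

    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def _scipy_merges(self) -> np.ndarray:
        # scipy consumers need monotone heights; ward.D heights are already
        # monotone, so the matrix is valid as-is
        return self.merges


def _nan_euclidean_pdist(X: np.ndarray) -> np.ndarray:
    """Pairwise-complete Euclidean distances, scaled for missing dims."""
    n, p = X.shape
    out = np.zeros(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(np.isnan(X[i]) | np.isnan(X[j]))
            m = int(mask.sum())
            if m == 0:
                raise ValueError(f"rows {i} and {j} share no observed cell line")
            diff = X[i, mask] - X[j, mask]
            out[k] = np.sqrt(np.dot(diff, diff) * p / m)
            k += 1
    return out


def hierarchical_cluster(
    matrix: pd.DataFrame | np.ndarray,
    distance: str = "euclidean",
    linkage_method: str = "average",
    missing: str = "zero",
) -> ClusterTree:
    """Cluster matrix rows (pass a transposed matrix for columns).

    ``missing="zero"`` imputes NaN entries as 0 before computing distances
    (0 = no splicing shift, the neutral value on the Δψ scale);
    ``missing="pairwise"`` uses pairwise-complete distances instead.
    Deterministic given the input row order.
    """
    if distance != "euclidean":
        raise ValueError("only euclidean distance is supported")
    if linkage_method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if isinstance(matrix, pd.DataFrame):
        labels = [str(i) for i in matrix.index]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if missing == "zero":
        d = pdist(np.nan_to_num(X, nan=0.0), metric="euclidean")
    elif missing == "pairwise":
        d = _nan_euclidean_pdist(X)
    else:
        raise ValueError("missing must be 'zero' or 'pairwise'")
    if linkage_method == "average":
        Z = linkage(d, method="average")
    else:
        Z = linkage(np.sqrt(d), method="ward")
        Z[:, 2] = Z[:, 2] ** 2  # back to ward.D heights on unsquared distances
    return ClusterTree(merges=Z, labels=labels, method=linkage_method)


def cut_k(tree: ClusterTree, k: int) -> pd.Series:
    """Flat clusters from cutting above the k−1 highest merges.

    Returns a Series mapping row label → cluster id in 1..k.
    """
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in [1, {tree.n_leaves}]")
    assignment = fcluster(tree._scipy_merges(), t=k, criterion="maxclust")
    return pd.Series(assignment, index=tree.labels, name="cluster")
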