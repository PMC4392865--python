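"""Structural diagnostics: lineage clustering, cross-dataset singular
vectors, and context-stratified correlations.

If the leading SVD terms really capture cell composition, the columns of
Delta_k^T should cluster by cell lineage, left singular vectors from
datasets sharing a tissue should be nearly collinear, and intercept
profiles should correlate across datasets once genomic-context strata are
removed.  These checks operationalise those expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "DendrogramResult",
    "cluster_coefficient_columns",
    "singular_vector_crossproducts",
    "stratified_correlation",
]


@dataclass
class DendrogramResult:
    """Ward dendrogram over coefficient columns with a Newick export."""

    linkage: np.ndarray
    labels: list

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"

    def first_split(self) -> tuple[set, set]:
        """Leaf labels of the two branches under the root merge."""
        tree = hierarchy.to_tree(self.linkage)

        def leaves(node):
            if node.is_leaf():
                return {self.labels[node.id]}
            return leaves(node.left) | leaves(node.right)

        return leaves(tree.left), leaves(tree.right)


def cluster_coefficient_columns(
    Delta: np.ndarray,
    labels=None,
    include_intercept: bool = False,
    legacy_ward: bool = False,
) -> DendrogramResult:
    """Ward/Euclidean hierarchical clustering of coefficient columns.

    Clusters the columns of Delta_k (i.e. the rows of Delta_k^T).  The
    intercept column (index 0) is dropped unless ``include_intercept`` —
    it represents the reference tissue profile, not a contrast.
    ``legacy_ward`` switches from the squared-distance Ward update
    (ward.D2 convention) to the unsquared-distance variant (ward.D).
    """
    Delta = np.asarray(Delta, dtype=float)
    if labels is None:
        labels = [f"col{j}" for j in range(Delta.shape[1])]
    labels = list(labels)
    if not include_intercept:
        Delta = Delta[:, 1:]
        labels = labels[1:]
    if Delta.shape[1] < 2:
        raise ValueError("need at least two coefficient columns to cluster")
    if legacy_ward:
        dist = pdist(Delta.T) ** 2
        Z = hierarchy.linkage(dist, method="ward")
    else:
        Z = hierarchy.linkage(Delta.T, method="ward")
    return DendrogramResult(linkage=Z, labels=labels)


def singular_vector_crossproducts(U_list, k_max: int, dataset_names=None):
    """|u_i . u_j| over the first ``k_max`` left singular vectors per dataset.

    All U matrices must share the CpG universe (same rows, same order);
    mismatched row counts raise.  Returns (matrix, labels) where labels
    are "<dataset>:<term>".
    """
    mats = [np.asarray(U, dtype=float) for U in U_list]
    rows = {U.shape[0] for U in mats}
    if len(rows) != 1:
        raise ValueError(
            "left singular vector matrices have different row dimensions; "
            "intersect the CpG universes upstream"
        )
    if dataset_names is None:
        dataset_names = [f"ds{i + 1}" for i in range(len(mats))]
    blocks = [U[:, : min(k_max, U.shape[1])] for U in mats]
    labels = [
        f"{name}:{j + 1}"
        for name, U in zip(dataset_names, blocks)
        for j in range(U.shape[1])
    ]
    stacked = np.hstack(blocks)
    return np.abs(stacked.T @ stacked), labels


def stratified_correlation(x, y, strata) -> float:
    """Pearson correlation after removing per-stratum means.

    x and y are centered within each stratum and the correlation is
    computed on the pooled centered values, so between-stratum offsets
    (e.g. CpG-island vs open-sea methylation levels) do not contribute.
    Returns NaN when every stratum is degenerate (zero variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    if not (x.size == y.size == strata.size):
        raise ValueError("x, y and strata must have equal length")
    sizes = [np.sum(strata == s) for s in np.unique(strata)]
    if max(sizes) < 3:
        raise ValueError("need at least 3 points in some stratum")
    xc = np.empty_like(x)
    yc = np.empty_like(y)
    for s in np.unique(strata):
        mask = strata == s
        xc[mask] = x[mask] - x[mask].mean()
        yc[mask] = y[mask] - y[mask].mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.sum(xc * yc) / (sx * sy))
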