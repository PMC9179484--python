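"""Hierarchical clustering of samples by multi-drug response profiles.

Samples are clustered on their per-treatment z-scored response vectors
(Euclidean distance, Ward linkage by default), the tree is cut to k
clusters, and cluster membership is related to treatment–treatment
correlations and to binary mutation status via the phi coefficient.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .types import MutationTable, ResponseTable

__all__ = [
    "ClusterAssignment",
    "cluster_responses",
    "correlate_treatments",
    "cluster_mutation_association",
    "linkage_to_newick",
]


@dataclass
class ClusterAssignment:
    sample_ids: list[str]
    linkage: np.ndarray
    k: int
    labels: np.ndarray  # cluster index (1..k) per sample

    def members(self, cluster_index: int) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.labels) if c == cluster_index]

    def membership_indicator(self, cluster_index: int) -> pd.Series:
        return pd.Series(
            (self.labels == cluster_index).astype(int), index=self.sample_ids
        )


def cluster_responses(
    response: ResponseTable,
    k: int = 4,
    zscore: bool = True,
    method: str = "ward",
) -> ClusterAssignment:
    """Agglomerative clustering of samples on (z-scored) response vectors."""
    n = len(response.sample_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    values = response.data.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("missing responses; impute before clustering")
    if zscore:
        mu = values.mean(axis=0, keepdims=True)
        sd = values.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
    dist = pdist(values, metric="euclidean")
    linkage = hierarchy.linkage(dist, method=method)
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return ClusterAssignment(
        sample_ids=list(response.sample_ids), linkage=linkage, k=k, labels=labels
    )


def correlate_treatments(
    response: ResponseTable, drug_a: str, drug_b: str
) -> dict:
    """Pearson r (and two-sided p) between two drugs across paired samples."""
    a = response.data[drug_a]
    b = response.data[drug_b]
    paired = pd.concat([a, b], axis=1).dropna()
    if len(paired) < 3:
        raise ValueError("need >= 3 paired response values")
    x = paired.iloc[:, 0].to_numpy()
    y = paired.iloc[:, 1].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a response vector; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(paired)),
            "drug_a": drug_a, "drug_b": drug_b}


def phi_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Phi for two binary vectors: (ad - bc) / sqrt of margin products."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    a = int(((x == 1) & (y == 1)).sum())
    b = int(((x == 1) & (y == 0)).sum())
    c = int(((x == 0) & (y == 1)).sum())
    d = int(((x == 0) & (y == 0)).sum())
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("constant indicator; phi undefined")
    return (a * d - b * c) / np.sqrt(denom)


def cluster_mutation_association(
    assignment: ClusterAssignment,
    mutations: MutationTable,
    cluster_index: int,
    gene_group: list[str] | None = None,
) -> dict:
    """Phi between cluster membership and any-mutation-in-group status.

    The phi coefficient equals the Pearson correlation of the two binary
    indicators; the two-sided p comes from the t approximation to r.
    """
    member = assignment.membership_indicator(cluster_index)
    flags = mutations.flags.loc[member.index]
    if gene_group is not None:
        missing = set(gene_group) - set(flags.columns)
        if missing:
            raise KeyError(f"mutation columns absent: {sorted(missing)}")
        flags = flags[list(gene_group)]
    any_mut = (flags.to_numpy().sum(axis=1) > 0).astype(int)
    x = member.to_numpy()
    r = phi_coefficient(x, any_mut)
    n = len(x)
    # t approximation for the significance of a Pearson correlation
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), df=n - 2)
    return {"r": float(r), "p": float(p), "n": n, "cluster": cluster_index}


def linkage_to_newick(assignment: ClusterAssignment) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    tree = hierarchy.to_tree(assignment.linkage)
    names = assignment.sample_ids

    def _build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = _build(node.left, node.dist)
        right = _build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _build(tree, tree.dist) + ";"
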