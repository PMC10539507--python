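"""Differential expression and correlation-distance hierarchical clustering."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .difftf import _pooled_ttest, _split_groups, bh_fdr
from .errors import DomainError, InsufficientDataError, ParameterError

__all__ = [
    "differential_expression",
    "correlation_distance",
    "hierarchical_cluster",
    "Dendrogram",
]


def differential_expression(
    expr: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Per-gene pooled t test between invasion groups with BH adjustment.

    Returns the per-gene table (feature_id, mean_low, mean_high, t_stat,
    p_value, q_value, direction) and the number of genes with
    q < ``fdr_threshold``.
    """
    labels = pd.Series(labels)
    shared = [s for s in expr.columns if s in labels.index]
    low, high = _split_groups(labels.loc[shared])
    if len(low) < 2 or len(high) < 2:
        raise InsufficientDataError("each group needs >= 2 samples")
    a = expr[low].to_numpy(dtype=float)
    b = expr[high].to_numpy(dtype=float)
    t, p = _pooled_ttest(a, b)
    q = bh_fdr(p)
    mean_low = a.mean(axis=1)
    mean_high = b.mean(axis=1)
    table = pd.DataFrame({
        "feature_id": expr.index,
        "mean_low": mean_low,
        "mean_high": mean_high,
        "t_stat": t,
        "p_value": p,
        "q_value": q,
        "direction": np.where(mean_high > mean_low, "promoting", "suppressing"),
    })
    deg_count = int((q < fdr_threshold).sum())
    return table, deg_count


def correlation_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - Pearson correlation; 0 for positively affinely related vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ParameterError("x and y must be equal-length with n >= 2")
    if x.std() == 0 or y.std() == 0:
        raise DomainError("zero variance; correlation distance undefined")
    return float(1.0 - np.corrcoef(x, y)[0, 1])


@dataclass
class Dendrogram:
    """Agglomerative merge history over samples.

    ``linkage_matrix`` is the standard (n-1) x 4 merge table (child ids,
    merge height, cluster size); ``leaf_ids`` maps leaf indices 0..n-1 to
    sample identifiers.
    """

    linkage_matrix: np.ndarray
    leaf_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Cut into k flat clusters; labels are 1..k."""
        flat = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.leaf_ids, name="cluster")

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.10g}"
            inner = ",".join(
                render(child, node.dist) for child in (node.left, node.right)
            )
            return f"({inner}):{length:.10g}"

        inner = ",".join(render(child, tree.dist) for child in (tree.left, tree.right))
        return f"({inner});"


def hierarchical_cluster(
    matrix: pd.DataFrame,
    linkage: str = "average",
    top_variance: int | None = None,
) -> Dendrogram:
    """Cluster samples (columns) by correlation distance.

    ``top_variance`` optionally restricts the distance computation to the
    given number of most variable genes; by default every gene contributes.
    """
    if matrix.shape[1] < 2:
        raise InsufficientDataError("clustering needs >= 2 samples")
    if top_variance is not None:
        keep = matrix.var(axis=1).nlargest(top_variance).index
        matrix = matrix.loc[keep]
    x = matrix.to_numpy(dtype=float).T
    if np.any(x.std(axis=1) == 0):
        raise DomainError("constant sample vector; correlation distance undefined")
    d = pdist(x, metric="correlation")
    d = np.clip(d, 0.0, None)  # guard tiny negative rounding
    z = hierarchy.linkage(d, method=linkage)
    return Dendrogram(linkage_matrix=z, leaf_ids=[str(c) for c in matrix.columns])
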