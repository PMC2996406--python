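"""Hierarchical clustering of expression profiles.

Samples (or transcripts) are clustered agglomeratively with average linkage
(UPGMA) on the uncentered correlation distance

    d(x, y) = 1 - (sum x_i y_i) / (||x|| * ||y||),

i.e. one minus the cosine similarity without mean-centering.  The distance
is scale-invariant per profile and lives in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .matrix import ExpressionMatrix

__all__ = ["uncentered_correlation_distance", "hier_cluster", "Dendrogram"]


def uncentered_correlation_distance(x, y) -> float:
    """Uncentered (cosine-type) correlation distance between two profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("profiles must be equal-length vectors of length >= 2")
    nx = np.sqrt((x * x).sum())
    ny = np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        raise ValueError("uncentered correlation undefined for a zero-norm vector")
    return float(1.0 - (x * y).sum() / (nx * ny))


@dataclass
class Dendrogram:
    """Average-linkage tree in scipy linkage-matrix form.

    ``linkage`` has one row per merge: the two merged node ids, the merge
    height (average inter-cluster distance) and the new cluster size.
    """

    linkage: np.ndarray
    labels: list[str]
    axis: str

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights decreased: linkage is not monotone")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels (1..k) from cutting the tree into k clusters."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels)

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                name = str(self.labels[node.id]).replace(" ", "_")
                return f"{name}:{parent_height:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def hier_cluster(
    matrix: ExpressionMatrix,
    axis: str = "samples",
    transcripts=None,
    log2: bool = False,
    center: bool = False,
    absent_fill: float = 50.0,
) -> Dendrogram:
    """UPGMA clustering of samples or transcripts by expression profile.

    ``transcripts`` optionally restricts the profiles to a subset (e.g. the
    significant transcripts, as in a heat-map of differential expression).
    Absent cells are filled with the detection-floor value before computing
    distances; ``log2`` applies a log2 transform first and ``center``
    subtracts each transcript's mean across samples (the usual heat-map
    preprocessing, which stops high-baseline transcripts from dominating the
    distances).  The default is untransformed normalized intensities.
    """
    m = matrix if transcripts is None else matrix.subset_transcripts(transcripts)
    data = m.intensity.to_numpy(dtype=float)
    data = np.where(np.isnan(data), absent_fill, data)
    if log2:
        if np.any(data <= 0):
            raise ValueError("log2 transform requires strictly positive intensities")
        data = np.log2(data)
    if center:
        data = data - data.mean(axis=1, keepdims=True)
    if axis == "samples":
        profiles = data.T
        labels = [str(c) for c in m.intensity.columns]
    elif axis == "transcripts":
        profiles = data
        labels = [str(i) for i in m.intensity.index]
    else:
        raise ValueError("axis must be 'samples' or 'transcripts'")
    if len(labels) < 2:
        raise ValueError("need at least two profiles to cluster")
    norms = np.sqrt((profiles**2).sum(axis=1))
    if np.any(norms == 0):
        bad = labels[int(np.argmin(norms))]
        raise ValueError(f"profile {bad!r} has zero norm; distance undefined")
    dist = pdist(profiles, metric="cosine")  # == uncentered correlation distance
    z = hierarchy.linkage(dist, method="average")
    return Dendrogram(linkage=z, labels=labels, axis=axis)
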