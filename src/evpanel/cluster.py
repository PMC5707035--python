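"""Hierarchical clustering with Pearson-correlation distance and Ward linkage.

Distances are d(x, y) = 1 - r(x, y), in [0, 2].  Because this dissimilarity
is not Euclidean, Ward's minimum-variance criterion is applied directly to
it via the Lance–Williams recurrence (the "ward.D" convention), rather than
to squared Euclidean distances.  Implementation detail: running scipy's
Ward linkage on sqrt(d) performs exactly that recurrence on d — scipy
squares the supplied dissimilarities inside its update — so merge order is
identical and the reported heights are recovered by squaring.  The method
tags on the dendrogram record this convention.

Profiles with zero variance have undefined correlation; gene-axis callers
typically drop them (``on_zero_variance="drop"``), sample-axis callers get
an error listing the offending items.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrix import AbundanceMatrix

__all__ = [
    "Dendrogram",
    "pearson_distance_matrix",
    "ward_linkage",
    "cut_tree",
    "to_newick",
]


def pearson_distance_matrix(
    matrix: AbundanceMatrix,
    axis: str = "samples",
    on_zero_variance: str = "error",
) -> pd.DataFrame:
    """Symmetric table of 1 - Pearson r between samples or gene profiles."""
    if axis not in ("samples", "genes"):
        raise ValueError("axis must be 'samples' or 'genes'")
    data = matrix.data.to_numpy(dtype=float)
    labels = matrix.samples if axis == "samples" else matrix.genes
    profiles = data.T if axis == "samples" else data  # rows = items
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 items to compute distances")
    sds = profiles.std(axis=1)
    flat = [labels[i] for i in np.flatnonzero(sds == 0)]
    if flat:
        if on_zero_variance == "drop":
            warnings.warn(f"dropping {len(flat)} zero-variance profiles: {flat[:10]}")
            keep = sds > 0
            profiles = profiles[keep]
            labels = [l for l, k in zip(labels, keep) if k]
            if profiles.shape[0] < 2:
                raise ValueError("fewer than 2 items left after dropping flat profiles")
        else:
            raise ValueError(f"zero-variance profiles (correlation undefined): {flat}")
    corr = np.corrcoef(profiles)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry against fp noise
    return pd.DataFrame(dist, index=labels, columns=labels)


@dataclasses.dataclass
class Dendrogram:
    """Agglomerative merge tree.

    ``merges`` follows the scipy linkage layout (left id, right id, height,
    cluster size) with heights on the scale of the input dissimilarity
    (ward.D convention).  Leaves are numbered 0..n-1 in ``labels`` order.
    """

    merges: np.ndarray
    labels: list[str]
    linkage_method: str = "ward.D"
    distance_method: str = "pearson"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def ward_linkage(distances: pd.DataFrame, distance_method: str = "pearson") -> Dendrogram:
    """Ward's minimum-variance agglomeration on a precomputed dissimilarity."""
    dist = np.asarray(distances, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance table must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance table must be symmetric")
    if (np.diag(dist) != 0).any():
        raise ValueError("distance table must have a zero diagonal")
    labels = [str(l) for l in distances.index]
    condensed = squareform(dist, checks=False)
    merges = linkage(np.sqrt(condensed), method="ward")
    merges = merges.copy()
    merges[:, 2] **= 2  # back to the ward.D height scale
    return Dendrogram(
        merges=merges,
        labels=labels,
        linkage_method="ward.D",
        distance_method=distance_method,
    )


def cut_tree(dend: Dendrogram, k: int) -> dict[str, int]:
    """Partition the leaves into k groups by undoing the k-1 highest merges.

    Cluster ids are renumbered 1..k by order of first appearance over the
    leaf labels, so assignments are stable across runs.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = fcluster(dend.merges, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for label, cid in zip(dend.labels, raw):
        if cid not in remap:
            remap[cid] = len(remap) + 1
        assignment[label] = remap[cid]
    return assignment


def to_newick(dend: Dendrogram) -> str:
    """Newick string with branch lengths derived from merge heights.

    A child's branch length is its parent's merge height minus its own
    (leaves have height 0).
    """
    n = dend.n_leaves
    heights = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for j, (a, b, h, _size) in enumerate(dend.merges):
        node = n + j
        heights[node] = float(h)
        children[node] = (int(a), int(b))

    def render(node: int, parent_height: float) -> str:
        length = max(parent_height - heights[node], 0.0)
        if node < n:
            return f"{dend.labels[node]}:{length:.6g}"
        left, right = children[node]
        inner = ",".join(render(c, heights[node]) for c in (left, right))
        return f"({inner}):{length:.6g}"

    root = n + len(children) - 1
    left, right = children[root]
    inner = ",".join(render(c, heights[root]) for c in (left, right))
    return f"({inner});"
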