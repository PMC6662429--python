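"""Edge thinning (percolation) over increasing link distance.

Points within a link radius r belong to the same cluster (single linkage,
transitive). As r grows from 0 the number of connected components falls from
n to 1; runs of r over which the count is constant ("plateaus") mark
threshold distances at which the spatial structure is minimally connected,
and the cluster labels at such a radius define nest aggregations for the
downstream hierarchical genetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .data_model import PointPattern

__all__ = [
    "ThinningProfile",
    "ThresholdDistance",
    "ClusterAssignment",
    "edge_thinning",
    "detect_plateaus",
    "assign_clusters",
]


@dataclass
class ThinningProfile:
    r_steps: np.ndarray
    n_clusters: np.ndarray
    mean_size: np.ndarray  # mean points per cluster (singletons included)


@dataclass
class ThresholdDistance:
    td: float  # plateau onset radius (meters)
    n_clusters: int
    length: int  # plateau extent in grid steps


@dataclass
class ClusterAssignment:
    radius: float
    labels: dict  # point id -> cluster id ("C1", "C2", ...)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def _component_labels(xy: np.ndarray, radius: float) -> np.ndarray:
    n = len(xy)
    if n == 0:
        return np.zeros(0, dtype=int)
    # radius 0 still links coincident points (<= convention)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")  # d <= radius (ties linked)
    if len(pairs) == 0:
        return np.arange(n)
    data = np.ones(len(pairs))
    graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def edge_thinning(pattern: PointPattern, step: float = 5.0, r_max: float = None) -> ThinningProfile:
    """Count connected components at link radii {0, step, 2*step, ..., r_max}.

    ``r_max`` defaults to the smallest multiple of ``step`` at or above the
    maximum pairwise distance, so the profile always ends at one cluster.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if pattern.n < 1:
        raise ValueError("edge_thinning requires at least 1 point")
    if r_max is None:
        if pattern.n == 1:
            r_max = step
        else:
            d = pattern.xy[:, None, :] - pattern.xy[None, :, :]
            dmax = np.hypot(d[..., 0], d[..., 1]).max()
            r_max = step * np.ceil(dmax / step)
    radii = np.arange(0.0, r_max + step / 2, step)
    counts = np.empty(len(radii), dtype=int)
    # sort pairwise distances once; component counts via incremental union-find
    parent = np.arange(pattern.n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if pattern.n >= 2:
        d = pattern.xy[:, None, :] - pattern.xy[None, :, :]
        dist = np.hypot(d[..., 0], d[..., 1])
        iu = np.triu_indices(pattern.n, 1)
        flat = dist[iu]
        order = np.argsort(flat)
        pairs = np.column_stack([iu[0][order], iu[1][order]])
        dists = flat[order]
    else:
        pairs = np.zeros((0, 2), dtype=int)
        dists = np.zeros(0)
    n_comp = pattern.n
    ptr = 0
    for k, r in enumerate(radii):
        while ptr < len(dists) and dists[ptr] <= r:
            a, b = find(pairs[ptr, 0]), find(pairs[ptr, 1])
            if a != b:
                parent[a] = b
                n_comp -= 1
            ptr += 1
        counts[k] = n_comp
    mean_size = pattern.n / counts
    return ThinningProfile(radii, counts, mean_size)


def detect_plateaus(profile: ThinningProfile, min_run: int = 2) -> list:
    """Maximal constant-count runs of length >= min_run.

    The initial all-singletons run (count == number of points at r = 0) is
    excluded as degenerate; each plateau is reported with its onset radius.
    """
    if min_run < 1:
        raise ValueError("min_run >= 1 required")
    counts = np.asarray(profile.n_clusters)
    if len(counts) == 0:
        raise ValueError("empty thinning profile")
    plateaus = []
    i = 0
    n_points = counts[0] if profile.r_steps[0] == 0 else None
    while i < len(counts):
        j = i
        while j + 1 < len(counts) and counts[j + 1] == counts[i]:
            j += 1
        run_len = j - i + 1
        is_singleton_prefix = i == 0 and n_points is not None and counts[i] == n_points
        if run_len >= min_run and not is_singleton_prefix:
            plateaus.append(
                ThresholdDistance(float(profile.r_steps[i]), int(counts[i]), run_len)
            )
        i = j + 1
    return plateaus


def assign_clusters(pattern: PointPattern, radius: float) -> ClusterAssignment:
    """Label points by the connected components of the <= radius link graph."""
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    labels = _component_labels(pattern.xy, radius)
    # stable relabeling in order of first appearance
    remap, out = {}, {}
    for pid, lab in zip(pattern.ids, labels):
        if lab not in remap:
            remap[lab] = f"C{len(remap) + 1}"
        out[pid] = remap[lab]
    return ClusterAssignment(radius, out)
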