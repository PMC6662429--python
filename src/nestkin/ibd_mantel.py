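"""Isolation by distance: Nei genetic distance vs geographic distance (Mantel).

Nei's standard genetic distance between two allele-frequency vectors is
D = -ln I, where I is the normalized identity
I = sum_loci sum_k x_k y_k / sqrt(sum x_k^2 * sum y_k^2) aggregated over loci
(ratio of sums across loci, the ``dist.genpop`` convention). Geographic
distances are straight-line meters between planar coordinates.

The Mantel statistic is the Pearson correlation of the upper-triangle entries
of the two matrices; significance comes from simultaneous row/column
permutations of one matrix, one-sided for positive association (isolation by
distance predicts genetic distance increasing with geographic distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import GenotypePanel, PointPattern

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "nei_distance",
    "euclidean_distance",
    "mantel_test",
]


@dataclass
class DistanceMatrix:
    ids: list
    values: np.ndarray
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=False):
            raise ValueError("distance matrix must have zero diagonal")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
        ):
            raise ValueError("distance matrix must be symmetric")


@dataclass
class MantelResult:
    r: float
    r2: float
    p: float
    permutations: int
    n_excluded_pairs: int = 0


def _group_frequencies(panel: GenotypePanel, group_by: str):
    """Per-locus (G, K_j) allele-frequency matrices and (G,) typed masks.

    Groups are ordered by first appearance; ``group_by`` may be a label
    column or "individual" (every individual its own frequency vector).
    """
    if group_by == "individual":
        group_of = np.arange(panel.n_individuals)
        groups = list(panel.individuals)
    else:
        labels = panel.labels[group_by]
        groups = [g for g in pd.unique(labels) if not pd.isna(g)]
        index = {g: i for i, g in enumerate(groups)}
        group_of = np.array(
            [index.get(l, -1) for l in labels], dtype=int
        )
    G = len(groups)
    freq_mats, typed_masks = [], []
    for j in range(panel.n_loci):
        g = panel.calls[:, j, :]
        mask = (g > 0).all(axis=1) & (group_of >= 0)
        alleles, codes = np.unique(g[mask].ravel(), return_inverse=True)
        counts = np.zeros((G, max(len(alleles), 1)))
        rows = np.repeat(group_of[mask], 2)
        np.add.at(counts, (rows, codes), 1.0)
        tot = counts.sum(axis=1, keepdims=True)
        typed = tot[:, 0] > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(typed[:, None], counts / np.where(tot > 0, tot, 1), 0.0)
        freq_mats.append(freq)
        typed_masks.append(typed)
    return groups, freq_mats, typed_masks


def nei_distance(panel: GenotypePanel, group_by: str = "nest") -> DistanceMatrix:
    """Nei's standard genetic distance D = -ln(I) between groups.

    Loci untyped in either group of a pair are dropped pairwise; disjoint
    allele sets across all shared loci give I = 0 and D = inf (flagged by the
    caller's exclusion policy in the Mantel test).
    """
    groups, freq_mats, typed_masks = _group_frequencies(panel, group_by)
    G = len(groups)
    if G < 2:
        raise ValueError("nei_distance needs >= 2 groups")
    any_typed = np.zeros(G, dtype=bool)
    for t in typed_masks:
        any_typed |= t
    if not any_typed.all():
        raise ValueError("a group has no typed individuals at any locus")
    NUM = np.zeros((G, G))
    JX = np.zeros((G, G))
    JY = np.zeros((G, G))
    for freq, typed in zip(freq_mats, typed_masks):
        ok = typed[:, None] & typed[None, :]
        NUM += np.where(ok, freq @ freq.T, 0.0)
        d = (freq**2).sum(axis=1)
        JX += np.where(ok, d[:, None], 0.0)
        JY += np.where(ok, d[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = NUM / np.sqrt(JX * JY)
        D = np.where(identity > 0, -np.log(np.maximum(identity, 1e-300)), np.inf)
    D = np.maximum(D, 0.0)  # identity can exceed 1 by float noise
    D[JX * JY == 0] = np.nan
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry against float noise
    return DistanceMatrix([str(g) for g in groups], D, "genetic_nei")


def euclidean_distance(pattern_or_ids, xy=None) -> DistanceMatrix:
    """Straight-line distances in meters.

    Accepts a :class:`PointPattern` or (ids, xy-array)."""
    if isinstance(pattern_or_ids, PointPattern):
        ids, coords = list(pattern_or_ids.ids), pattern_or_ids.xy
    else:
        ids, coords = list(pattern_or_ids), np.asarray(xy, dtype=float)
    d = coords[:, None, :] - coords[None, :, :]
    return DistanceMatrix([str(i) for i in ids], np.hypot(d[..., 0], d[..., 1]), "geographic_euclidean")


def mantel_test(
    a: DistanceMatrix,
    b: DistanceMatrix,
    permutations: int = 10_000,
    seed=None,
    on_nonfinite: str = "exclude",
) -> MantelResult:
    """One-sided Mantel test for positive association between two matrices.

    r is the Pearson correlation over upper-triangle entries; the null is
    simulated by simultaneous row/column permutation of the second matrix.
    Non-finite entries (e.g. infinite Nei distances) are excluded pairwise by
    default (``on_nonfinite="error"`` raises instead).
    p = (exceedances + 1) / (permutations + 1).
    """
    if list(a.ids) != list(b.ids):
        raise ValueError("matrices must share ids and order")
    n = len(a.ids)
    if n < 3:
        raise ValueError("mantel_test needs >= 3 ids")
    iu = np.triu_indices(n, 1)
    av, bv = a.values[iu], b.values[iu]
    finite = np.isfinite(av) & np.isfinite(bv)
    n_excl = int((~finite).sum())
    if n_excl and on_nonfinite == "error":
        raise ValueError(f"{n_excl} non-finite pairs")
    if np.nanstd(av[finite]) == 0 or np.nanstd(bv[finite]) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    def corr(bmat):
        bvv = bmat[iu]
        ok = np.isfinite(av) & np.isfinite(bvv)
        x, y = av[ok], bvv[ok]
        x = x - x.mean()
        y = y - y.mean()
        return float((x * y).sum() / math.sqrt((x**2).sum() * (y**2).sum()))

    r_obs = corr(b.values)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if corr(b.values[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return MantelResult(r_obs, r_obs**2, p, permutations, n_excl)
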