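"""The EACCD algorithm: initial dissimilarities, ensemble PAM, minimax linkage.

Given n factor-level combinations, the ensemble algorithm proceeds in three
steps:

1. an initial dissimilarity ``dis0`` between every pair of combinations (the
   Gehan–Wilcoxon effect size of their survival difference);
2. an ensemble step: for every k in 1..n, two-phase Partitioning Around
   Medoids (PAM) partitions the combinations into k clusters using ``dis0``;
   the learned dissimilarity of a pair is the weighted fraction of those n
   partitions that separate it;
3. agglomerative hierarchical clustering of the learned dissimilarities with
   the minimax linkage, which represents every cluster by a prototype
   combination and merges so as to keep the prototype-to-member radius small.

All three steps are deterministic: ties in medoid seeding, swaps, merges and
prototypes are broken by lowest label index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CombinationCohort
from .survival import effect_size_dissimilarity

__all__ = [
    "DissimilarityMatrix",
    "PartitionLabeling",
    "EnsembleWeights",
    "Merge",
    "Dendrogram",
    "initial_dissimilarity_matrix",
    "pam",
    "ensemble_dissimilarity",
    "minimax_linkage",
    "cut_dendrogram",
]


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric nonnegative pairwise dissimilarities between labeled items."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {values.shape}")
        if not np.isfinite(values).all():
            raise ValueError("dissimilarities must be finite")
        if (values < 0).any():
            raise ValueError("dissimilarities must be nonnegative")
        if not np.allclose(values, values.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def initial_dissimilarity_matrix(
    cohort: CombinationCohort, *, degenerate_value: float = 1.0
) -> DissimilarityMatrix:
    """Pairwise survival-difference dissimilarities between combinations.

    Entry (i, j) is the Gehan–Wilcoxon effect size between the observations
    of combination i and combination j; degenerate pairs (no determinate
    orderings) receive the sentinel value with a warning.
    """
    labels = cohort.labels
    if len(labels) < 2:
        raise ValueError("need at least two combinations")
    n = len(labels)
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = effect_size_dissimilarity(
            cohort.groups[labels[i]],
            cohort.groups[labels[j]],
            degenerate_value=degenerate_value,
        )
        values[i, j] = values[j, i] = d
    return DissimilarityMatrix(tuple(labels), values)


@dataclass(frozen=True)
class PartitionLabeling:
    """A flat k-clustering: label -> 1-based cluster id, one medoid per cluster."""

    k: int
    assignment: dict[str, int]
    medoids: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = set(self.assignment.values())
        if ids != set(range(1, self.k + 1)):
            raise ValueError("cluster ids must be exactly 1..k with no empty cluster")
        if len(self.medoids) != self.k:
            raise ValueError("need exactly one medoid per cluster")

    def members(self, cluster_id: int) -> list[str]:
        return [l for l, c in self.assignment.items() if c == cluster_id]

    def as_array(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[l] for l in labels])


class EnsembleWeights:
    """Nonnegative weights over the ensemble's k = 1..n partitions, summing to 1."""

    def __init__(self, weights: Sequence[float]):
        w = np.asarray(weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
        self.values = w

    @classmethod
    def equal(cls, n: int) -> "EnsembleWeights":
        return cls(np.full(n, 1.0 / n))

    def __len__(self) -> int:
        return self.values.size


def _pam_cost(values: np.ndarray, medoids: Sequence[int]) -> float:
    return float(values[:, list(medoids)].min(axis=1).sum())


def pam(d: DissimilarityMatrix, k: int) -> PartitionLabeling:
    """Two-phase Partitioning Around Medoids (BUILD then SWAP).

    BUILD seeds the k medoids greedily: the first minimizes the total
    dissimilarity to all points, each later one maximizes the reduction in
    total point-to-nearest-medoid cost.  SWAP then repeatedly applies the
    single best strictly improving (medoid, non-medoid) exchange until none
    exists.  Every tie (seeding, swap choice, nearest-medoid assignment) is
    broken by lowest label index, making the result deterministic.
    """
    n = d.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    values = d.values

    medoids = [int(np.argmin(values.sum(axis=1)))]
    while len(medoids) < k:
        cost_now = values[:, medoids].min(axis=1)
        best_gain, best_c = -np.inf, None
        for c in range(n):
            if c in medoids:
                continue
            gain = float(np.maximum(cost_now - values[:, c], 0.0).sum())
            if gain > best_gain + 1e-12:
                best_gain, best_c = gain, c
        medoids.append(best_c)

    cost = _pam_cost(values, medoids)
    improved = True
    while improved:
        improved = False
        best = None  # (cost, medoid position, candidate)
        for mi, m in enumerate(sorted(medoids)):
            pos = medoids.index(m)
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[pos] = h
                trial_cost = _pam_cost(values, trial)
                if trial_cost < cost - 1e-12 and (best is None or trial_cost < best[0] - 1e-12):
                    best = (trial_cost, pos, h)
        if best is not None:
            cost, pos, h = best
            medoids[pos] = h
            improved = True

    medoids = sorted(medoids)
    nearest = np.argmin(values[:, medoids], axis=1)  # ties -> lowest medoid index
    # a medoid anchors its own cluster even if another medoid is at distance 0
    for pos, m in enumerate(medoids):
        nearest[m] = pos
    assignment = {d.labels[i]: int(nearest[i]) + 1 for i in range(n)}
    return PartitionLabeling(
        k=k,
        assignment=assignment,
        medoids=tuple(d.labels[m] for m in medoids),
    )


def ensemble_dissimilarity(
    d0: DissimilarityMatrix, weights: EnsembleWeights | None = None
) -> DissimilarityMatrix:
    """Learned (ensemble) dissimilarity from PAM partitions at every k.

    For each k in 1..n, PAM partitions the items using ``d0``; the separation
    indicator delta_k(i, j) is 1 when i and j land in different clusters.
    The learned dissimilarity is ``sum_k w_k * delta_k(i, j)`` — with equal
    weights, the fraction of ensemble partitions that separate the pair.
    Off-diagonal entries are therefore bounded by [w_n, 1 - w_1]: k = 1 never
    separates a pair and k = n always does.
    """
    n = d0.n
    weights = EnsembleWeights.equal(n) if weights is None else weights
    if len(weights) != n:
        raise ValueError(f"need {n} weights, got {len(weights)}")
    learned = np.zeros((n, n))
    for k in range(1, n + 1):
        part = pam(d0, k)
        ids = part.as_array(d0.labels)
        separated = ids[:, None] != ids[None, :]
        learned += weights.values[k - 1] * separated
    np.fill_diagonal(learned, 0.0)
    return DissimilarityMatrix(d0.labels, learned)


@dataclass(frozen=True)
class Merge:
    """One agglomeration: children are node ids (leaves 0..n-1, merges n..2n-2)."""

    left: int
    right: int
    height: float
    prototype: str


@dataclass(frozen=True)
class Dendrogram:
    """Minimax-linkage merge tree over combination labels.

    Node ids follow the scipy convention: leaf i is node i; the j-th merge
    creates node n + j.  Each merge records its minimax radius as the height
    and the prototype (the leaf whose maximum dissimilarity to the merged
    cluster attains that radius).
    """

    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    @property
    def n(self) -> int:
        return len(self.leaves)

    def leaves_under(self, node: int) -> list[int]:
        n = self.n
        if node < n:
            return [node]
        merge = self.merges[node - n]
        return self.leaves_under(merge.left) + self.leaves_under(merge.right)

    def to_linkage(self) -> np.ndarray:
        """Scipy-style (n-1) x 4 linkage matrix (for plotting)."""
        sizes = {}
        z = np.zeros((self.n - 1, 4))
        for j, merge in enumerate(self.merges):
            size = len(self.leaves_under(self.n + j))
            sizes[self.n + j] = size
            z[j] = [merge.left, merge.right, merge.height, size]
        return z

    def to_newick(self) -> str:
        """Newick string; branch lengths span between parent and child heights."""

        def height_of(node: int) -> float:
            return 0.0 if node < self.n else self.merges[node - self.n].height

        def render(node: int, parent_height: float) -> str:
            length = parent_height - height_of(node)
            if node < self.n:
                return f"{self.leaves[node]}:{length:.10g}"
            merge = self.merges[node - self.n]
            inner = ",".join(
                render(child, height_of(node)) for child in (merge.left, merge.right)
            )
            return f"({inner}):{length:.10g}"

        root = 2 * self.n - 2
        merge = self.merges[-1]
        inner = ",".join(render(c, self.merges[-1].height) for c in (merge.left, merge.right))
        return f"({inner});"

    def to_dict(self) -> dict:
        return {
            "leaves": list(self.leaves),
            "merges": [
                {
                    "left": m.left,
                    "right": m.right,
                    "height": m.height,
                    "prototype": m.prototype,
                }
                for m in self.merges
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _minimax_radius(values: np.ndarray, members: list[int]) -> tuple[float, int]:
    """Smallest possible max distance from one member (the prototype) to all."""
    sub = values[np.ix_(members, members)]
    radii = sub.max(axis=1)
    best = int(np.argmin(radii))  # ties -> lowest position = lowest label index
    return float(radii[best]), members[best]


def minimax_linkage(d: DissimilarityMatrix) -> Dendrogram:
    """Agglomerative clustering with the minimax (prototype) linkage.

    The cost of merging clusters G and H is the minimax radius of G ∪ H:
    ``min over p in G∪H of max over x in G∪H of d(p, x)``.  At each step the
    cheapest merge is performed (ties by the lowest pair of smallest-leaf
    representatives) and its prototype recorded.  Minimax linkage heights can
    occasionally invert; inversions are kept as computed and flagged with a
    warning, since cutting is by merge count and stays well defined.
    """
    n = d.n
    if n < 2:
        raise ValueError("need at least two items to build a dendrogram")
    values = d.values
    # active clusters: node id -> (sorted member leaf indices)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[Merge] = []
    next_id = n
    while len(active) > 1:
        best = None  # (cost, rep_a, rep_b, id_a, id_b)
        for id_a, id_b in combinations(sorted(active), 2):
            members = sorted(active[id_a] + active[id_b])
            cost, _ = _minimax_radius(values, members)
            rep_a, rep_b = min(active[id_a]), min(active[id_b])
            key = (cost, min(rep_a, rep_b), max(rep_a, rep_b))
            if best is None or key < best[0]:
                best = (key, id_a, id_b)
        (cost, _, _), id_a, id_b = best
        members = sorted(active[id_a] + active[id_b])
        _, proto = _minimax_radius(values, members)
        left, right = sorted((id_a, id_b), key=lambda i: min(active[i]))
        merges.append(Merge(left=left, right=right, height=cost, prototype=d.labels[proto]))
        active[next_id] = members
        del active[id_a], active[id_b]
        next_id += 1
    heights = [m.height for m in merges]
    if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
        warnings.warn("minimax linkage produced non-monotone merge heights", stacklevel=2)
    return Dendrogram(leaves=d.labels, merges=tuple(merges))


def cut_dendrogram(tree: Dendrogram, k: int) -> PartitionLabeling:
    """Cut a dendrogram into exactly k clusters by undoing the last k-1 merges.

    Each resulting cluster's representative is the prototype of the merge that
    formed it (the leaf itself for singletons).  Cluster ids are assigned
    1..k in order of each cluster's smallest leaf index.
    """
    n = tree.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    roots: dict[int, list[int]] = {i: [i] for i in range(n)}
    for j, merge in enumerate(tree.merges[: n - k]):
        roots[n + j] = sorted(roots.pop(merge.left) + roots.pop(merge.right))
    clusters = sorted(roots.items(), key=lambda item: min(item[1]))
    assignment: dict[str, int] = {}
    medoids: list[str] = []
    for cid, (node, members) in enumerate(clusters, start=1):
        for leaf in members:
            assignment[tree.leaves[leaf]] = cid
        if node < n:
            medoids.append(tree.leaves[node])
        else:
            medoids.append(tree.merges[node - n].prototype)
    return PartitionLabeling(k=k, assignment=assignment, medoids=tuple(medoids))
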