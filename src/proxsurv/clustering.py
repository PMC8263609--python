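"""Forest-proximity clustering of patients.

Proximity between two training patients is the fraction of trees, among
those where both are in the bootstrap sample, in which they share a terminal
node.  The dissimilarity ``D = 1 - P`` is fed to agglomerative Ward
clustering implemented directly on the precomputed matrix via the
Lance-Williams recurrence

    d(a+b, c) = [ (n_a + n_c) d(a,c) + (n_b + n_c) d(b,c) - n_c d(a,b) ]
                / (n_a + n_b + n_c)

with the recorded merge height delta = d(a,b) / 2, i.e. the Ward objective
|c1||c2| / (|c1| + |c2|) * ||mean(c1) - mean(c2)||^2 when the input entries
are interpreted as squared Euclidean distances (the "ward.D" dialect, the
default here).  A config switch squares the entries first ("ward.D2").

Ward on a forest dissimilarity is a heuristic: the matrix is not Euclidean
in general, but the recurrence is well defined on any symmetric
dissimilarity and in practice yields balanced, reproducible clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forest import SurvivalForest

__all__ = [
    "ProximityMatrix",
    "Dendrogram",
    "ClusterLabels",
    "inbag_proximity",
    "proximity_to_dissimilarity",
    "ward_agglomerate",
    "cut_dendrogram",
]

logger = logging.getLogger(__name__)


@dataclass
class ProximityMatrix:
    """Symmetric in-bag proximity plus the co-in-bag tree counts."""

    values: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        v, c = self.values, self.pair_counts
        if not np.allclose(v, v.T) or not np.array_equal(c, c.T):
            raise ValueError("proximity matrices must be symmetric")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("proximities must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("proximity diagonal must be 1")


@dataclass
class Dendrogram:
    """Merge list ``(id_a, id_b, height, new_size)``; leaves are 0..n-1 and
    the merge at step s creates cluster ``n + s`` (scipy convention)."""

    merges: list[tuple[int, int, float, int]]
    n_leaves: int

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves has n - 1 merges")

    @property
    def heights(self) -> np.ndarray:
        return np.asarray([h for _, _, h, _ in self.merges])

    def to_dict(self) -> dict:
        return {
            "n_leaves": self.n_leaves,
            "merges": [[int(a), int(b), float(h), int(s)] for a, b, h, s in self.merges],
        }


@dataclass
class ClusterLabels:
    """1-based labels numbered by decreasing cluster size (1 = largest)."""

    k: int
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(self.labels))
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"labels must occupy 1..{self.k}, got {sorted(present)}")

    def sizes(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in range(1, self.k + 1)}


def inbag_proximity(forest: SurvivalForest) -> ProximityMatrix:
    """Proximity over training patients from co-occupied terminal nodes.

    ``values[i, j]`` = (trees where i, j both in-bag and share a leaf) /
    (trees where both in-bag).  Pairs never co-in-bag (vanishingly rare at
    hundreds of trees) get proximity 0 with a logged warning.
    """
    ids = forest.training_node_ids  # (n, T)
    inbag = forest.inbag_matrix > 0  # (n, T)
    n = forest.n_train
    same_count = np.zeros((n, n), dtype=np.int64)
    both_count = np.zeros((n, n), dtype=np.int64)
    for t in range(forest.n_trees):
        b = inbag[:, t]
        both = np.logical_and(b[:, None], b[None, :])
        same = ids[:, t][:, None] == ids[:, t][None, :]
        both_count += both
        same_count += np.logical_and(both, same)
    values = np.zeros((n, n))
    pos = both_count > 0
    values[pos] = same_count[pos] / both_count[pos]
    np.fill_diagonal(values, 1.0)
    if np.any(~pos[np.triu_indices(n, k=1)]):
        logger.warning(
            "%d patient pair(s) never co-in-bag; proximity set to 0",
            int((~pos[np.triu_indices(n, k=1)]).sum()),
        )
    return ProximityMatrix(values=values, pair_counts=both_count)


def proximity_to_dissimilarity(P: ProximityMatrix) -> np.ndarray:
    """D = 1 - P entrywise (zero diagonal, symmetric)."""
    D = 1.0 - P.values
    np.fill_diagonal(D, 0.0)
    return D


def ward_agglomerate(D: np.ndarray, dialect: str = "ward.D") -> Dendrogram:
    """Agglomerate a precomputed dissimilarity with Ward linkage.

    ``dialect='ward.D'`` treats entries of ``D`` as squared distances;
    ``'ward.D2'`` squares them first.  Ties are broken by the smallest
    ``(id_a, id_b)`` cluster-id pair.
    """
    D = np.asarray(D, dtype=float)
    if np.isnan(D).any():
        raise ValueError("dissimilarity contains NaN")
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("D must be symmetric, non-negative with zero diagonal")
    if dialect not in ("ward.D", "ward.D2"):
        raise ValueError("dialect must be 'ward.D' or 'ward.D2'")
    n = D.shape[0]
    work = D.copy() if dialect == "ward.D" else D**2

    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=float)
    cluster_id = np.arange(n)  # current id held by each slot
    merges: list[tuple[int, int, float, int]] = []
    big = np.inf

    for step in range(n - 1):
        M = np.where(active[:, None] & active[None, :], work, big)
        np.fill_diagonal(M, big)
        dmin = M.min()
        # candidate slots at the minimum; break ties by smallest cluster-id pair
        ii, jj = np.where(M == dmin)
        pairs = [
            (min(cluster_id[i], cluster_id[j]), max(cluster_id[i], cluster_id[j]), i, j)
            for i, j in zip(ii, jj)
            if i < j
        ]
        ida, idb, a, b = min(pairs)
        na, nb = sizes[a], sizes[b]
        nc = sizes  # vector over slots
        # Lance-Williams update for Ward, written for every other slot at once
        new_row = ((na + nc) * work[a] + (nb + nc) * work[b] - nc * dmin) / (na + nb + nc)
        work[a] = new_row
        work[:, a] = new_row
        work[a, a] = 0.0
        active[b] = False
        sizes[a] = na + nb
        cluster_id[a] = n + step
        merges.append((int(ida), int(idb), float(dmin / 2.0), int(na + nb)))

    heights = np.asarray([h for _, _, h, _ in merges])
    if np.any(np.diff(heights) < -1e-9):
        logger.warning("non-monotone Ward merge heights encountered")
    return Dendrogram(merges=merges, n_leaves=n)


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> ClusterLabels:
    """Undo the last ``k - 1`` merges; number clusters by decreasing size."""
    n = dendrogram.n_leaves
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, _, _) in enumerate(dendrogram.merges[: n - k]):
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new

    roots = [find(i) for i in range(n)]
    uniq = {}
    raw = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        raw[i] = uniq.setdefault(r, len(uniq))
    # relabel by decreasing size; ties by smallest first-member index
    order = sorted(
        range(len(uniq)),
        key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c))),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    return ClusterLabels(k=k, labels=np.array([remap[c] for c in raw]))
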