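"""Agglomerative clustering over precomputed dissimilarity matrices.

The engine is a deterministic bottom-up merger: start from singleton
clusters, repeatedly merge the closest pair, and update inter-cluster
dissimilarities with the single (min), complete (max) or average
(mean over member pairs) linkage rule.  Cutting the merge sequence
when k clusters remain yields the partition.  Ties on the merge
distance are broken by the smallest pair of cluster creation indices,
so results are reproducible across runs and platforms.

Ward linkage is deliberately not offered: it presumes Euclidean
dissimilarities, which structure-comparison methods generally do not
produce.  The naive O(n^3) update is adequate at benchmark scale
(n of a few hundred).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINKAGES = ("single", "complete", "average")

#: tolerance under which an asymmetric matrix is silently symmetrised
SYMMETRY_TOL = 1e-9


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric zero-diagonal matrix of pairwise dissimilarities."""

    ids: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ClusteringError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.all(np.isfinite(v)):
            raise ClusteringError("non-finite dissimilarities")
        if np.any(v < 0):
            raise ClusteringError("negative dissimilarities")
        asym = np.abs(v - v.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            raise ClusteringError(f"matrix asymmetry {asym} exceeds tolerance")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DistanceMatrix":
        ids = tuple(str(c) for c in frame.columns)
        if tuple(str(i) for i in frame.index) != ids:
            raise ClusteringError("row and column IDs differ")
        return cls(ids=ids, values=frame.to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))


@dataclass(frozen=True)
class Dendrogram:
    """Merge list (cluster-a, cluster-b, height); clusters numbered as
    in scipy: 0..n-1 are singletons, merge t creates cluster n+t."""

    n: int
    merges: Tuple[Tuple[int, int, float], ...]


@dataclass(frozen=True)
class Partition:
    """Cluster index in [0, k) per molecule ID."""

    labels: Dict[str, int]

    def as_list(self, ids: Sequence[str]) -> List[int]:
        return [self.labels[str(i)] for i in ids]

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def agglomerative_cluster(
    D: DistanceMatrix, k: int, linkage: str = "average"
) -> Tuple[Dendrogram, Partition]:
    """Cluster the molecules of *D* into *k* groups.

    Returns the full dendrogram (n-1 merges) and the partition obtained
    by cutting it after n-k merges.
    """
    if linkage not in LINKAGES:
        raise ClusteringError(f"unknown linkage {linkage!r}; use one of {LINKAGES}")
    n = D.n
    if not (1 <= k <= n):
        raise ClusteringError(f"k={k} out of range 1..{n}")

    # active clusters: creation index -> member row indices
    members: Dict[int, List[int]] = {i: [i] for i in range(n)}
    dist: Dict[Tuple[int, int], float] = {}
    for a in range(n):
        for b in range(a + 1, n):
            dist[(a, b)] = float(D.values[a, b])

    merges: List[Tuple[int, int, float]] = []
    partition_at_k: Dict[str, int] | None = None
    next_id = n
    for step in range(n - 1):
        if len(members) == k:
            partition_at_k = _partition_labels(D.ids, members)
        # closest pair; ties by smallest (a, b) creation indices
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        ma, mb = members.pop(a), members.pop(b)
        new = ma + mb
        for c in list(members):
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            da, db = dist.pop(key_a), dist.pop(key_b)
            if linkage == "single":
                d = min(da, db)
            elif linkage == "complete":
                d = max(da, db)
            else:  # average: weighted by member counts
                d = (da * len(ma) + db * len(mb)) / (len(ma) + len(mb))
            dist[(c, next_id)] = d
        del dist[(a, b)]
        members[next_id] = new
        merges.append((a, b, h))
        next_id += 1
    if len(members) == k:  # k == 1
        partition_at_k = _partition_labels(D.ids, members)
    if partition_at_k is None:  # k == n: no merges consumed
        partition_at_k = {str(D.ids[i]): i for i in range(n)}
    return Dendrogram(n=n, merges=tuple(merges)), Partition(partition_at_k)


def _partition_labels(
    ids: Sequence[str], members: Dict[int, List[int]]
) -> Dict[str, int]:
    labels: Dict[str, int] = {}
    for cluster_index, cid in enumerate(sorted(members)):
        for row in members[cid]:
            labels[str(ids[row])] = cluster_index
    return labels


def similarity_to_dissimilarity(S: np.ndarray, ids: Sequence[str]) -> DistanceMatrix:
    """Convert a similarity matrix: min-max normalise, then diss = 1 - sim.

    A constant matrix has zero range; it maps to all-zero
    dissimilarities with a warning.
    """
    S = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ClusteringError("non-finite similarities")
    lo, hi = S.min(), S.max()
    if hi - lo == 0:
        logger.warning("constant similarity matrix: all dissimilarities set to 0")
        diss = np.zeros_like(S)
    else:
        diss = 1.0 - (S - lo) / (hi - lo)
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    return DistanceMatrix(ids=tuple(ids), values=diss)


def num_clusters_from_labels(labels: Sequence[str]) -> int:
    """Number of distinct taxon labels = requested cluster count."""
    if len(labels) == 0:
        raise ClusteringError("empty label list")
    return len(set(labels))
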