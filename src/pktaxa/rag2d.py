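"""RAG-2D: dual-graph spectral features of a secondary structure.

The dual graph of a structure has one vertex per stem and one edge per
single-stranded segment of more than one unpaired nucleotide, joining
the stems that flank the segment (a self-loop when both flanks belong
to the same stem, e.g. a hairpin loop).  The 5' and 3' dangling ends
contribute nothing.  A stem is a maximal helix; by default two helices
separated by a bulge or internal loop of at most one unpaired
nucleotide per strand are merged into a single vertex, consistent with
the "more than one unpaired nucleotide" edge threshold.

From the graph Laplacian ``L = D - A`` (a self-loop contributes 2 to
both its adjacency and degree entry, so rows still sum to zero) the
Fiedler value and vector are extracted and condensed into two scalars:
sort the unit-norm Fiedler vector ascending, scale each component by
``(n-1)/(v_n - v_1)``, regress the scaled components on their ranks,
and keep the slope ``s`` and the mean squared residual ``e``.  The
distance between two molecules is the Euclidean distance between their
``(s, e)`` points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .io import SecondaryStructure
from .topology import extract_regions

logger = logging.getLogger(__name__)


class DualGraphError(ValueError):
    """Raised for structures or graphs outside the method's domain."""


@dataclass(frozen=True)
class DualGraph:
    """Multigraph with self-loops: one vertex per stem."""

    n_vertices: int
    edges: Tuple[Tuple[int, int], ...]  # unordered pairs, i <= j; multiset

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if not (0 <= i <= j < self.n_vertices):
                raise DualGraphError(f"edge ({i}, {j}) out of range")

    def relabelled(self, perm: Sequence[int]) -> "DualGraph":
        """Apply a vertex permutation (perm[old] = new)."""
        edges = tuple(
            sorted((tuple(sorted((perm[i], perm[j]))) for i, j in self.edges))
        )
        return DualGraph(self.n_vertices, edges)

    def is_connected(self) -> bool:
        if self.n_vertices <= 1:
            return True
        adj: List[set] = [set() for _ in range(self.n_vertices)]
        for i, j in self.edges:
            if i != j:
                adj[i].add(j)
                adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for u in adj[stack.pop()]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        return len(seen) == self.n_vertices


def _stems(structure: SecondaryStructure, merge_gap: int) -> List[List[tuple]]:
    """Group helices into stems.

    Starts from maximal stacks and merges a stack with one directly
    nested inside it when the two intervening strands both have at most
    ``merge_gap`` unpaired nucleotides and no other paired base lies
    between them.
    """
    regions = extract_regions(structure)
    if not regions:
        raise DualGraphError("structure has no stems")
    paired = set()
    for i, j in structure.pairs:
        paired.update((i, j))

    def clear(lo: int, hi: int) -> bool:  # open interval free of paired bases
        return all(p not in paired for p in range(lo + 1, hi))

    parent = list(range(len(regions)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, ra in enumerate(regions):
        ia, ja = ra.pairs[-1]  # innermost pair of the outer stack
        for b, rb in enumerate(regions):
            if a == b:
                continue
            ib, jb = rb.span
            if not (ia < ib and jb < ja):
                continue  # rb not nested inside ra's innermost pair
            gap5 = ib - ia - 1
            gap3 = ja - jb - 1
            if gap5 <= merge_gap and gap3 <= merge_gap:
                if clear(ia, ib) and clear(jb, ja):
                    parent[find(a)] = find(b)
    groups: dict[int, List[tuple]] = {}
    for k, region in enumerate(regions):
        groups.setdefault(find(k), []).extend(region.pairs)
    return list(groups.values())


def build_dual_graph(
    structure: SecondaryStructure, merge_gap: int = 1
) -> DualGraph:
    """Dual graph of *structure*.

    Every maximal unpaired run of more than one nucleotide strictly
    inside the backbone yields one edge between the stems of its two
    flanking paired positions; runs touching the 5' or 3' end are
    dangling and ignored.
    """
    stems = _stems(structure, merge_gap)
    stem_of = {}
    for v, pairs in enumerate(stems):
        for i, j in pairs:
            stem_of[i] = v
            stem_of[j] = v
    n = structure.length
    paired = set(stem_of)
    edges: List[Tuple[int, int]] = []
    run_start = None
    for pos in range(1, n + 2):
        unpaired = pos <= n and pos not in paired
        if unpaired and run_start is None:
            run_start = pos
        elif not unpaired and run_start is not None:
            run_end = pos - 1
            run_start_, run_start = run_start, None
            if run_start_ == 1 or run_end == n:
                continue  # dangling end: no representation
            if run_end - run_start_ + 1 > 1:
                a = stem_of[run_start_ - 1]
                b = stem_of[run_end + 1]
                edges.append(tuple(sorted((a, b))))
    return DualGraph(len(stems), tuple(sorted(edges)))


# ---------------------------------------------------------------------------
# spectral features
# ---------------------------------------------------------------------------

def laplacian(graph: DualGraph) -> np.ndarray:
    """Laplacian ``L = D - A`` with the self-loop convention a_ii = 2."""
    n = graph.n_vertices
    A = np.zeros((n, n))
    for i, j in graph.edges:
        if i == j:
            A[i, i] += 2.0
        else:
            A[i, j] += 1.0
            A[j, i] += 1.0
    D = np.diag(A.sum(axis=1))
    return D - A


@dataclass(frozen=True)
class FiedlerFeatures:
    """Spectral summary of a dual graph: regression slope and MSE."""

    fiedler_value: float
    s: float
    e: float
    scaled_components: Tuple[float, ...] = ()


def fiedler_features(graph: DualGraph, tol: float = 1e-9) -> FiedlerFeatures:
    """Compute the (s, e) features of a connected dual graph.

    Degenerate single-vertex graphs get sentinel features (0, 0); a
    disconnected graph (Fiedler value 0) is an error.
    """
    n = graph.n_vertices
    if n < 2:
        logger.warning("dual graph with %d vertex: sentinel features (0, 0)", n)
        return FiedlerFeatures(0.0, 0.0, 0.0)
    L = laplacian(graph)
    eigvals, eigvecs = np.linalg.eigh(L)
    lam2 = float(eigvals[1])
    if lam2 <= tol:
        raise DualGraphError("disconnected dual graph: Fiedler value is 0")
    mu2 = eigvecs[:, 1]
    mu2 = mu2 / np.linalg.norm(mu2)
    # sign convention: orient so the sorted vector is lexicographically
    # smallest (first component the most negative)
    v_plus = np.sort(mu2)
    v_minus = np.sort(-mu2)
    v = v_plus if tuple(v_plus) <= tuple(v_minus) else v_minus
    spread = float(v[-1] - v[0])
    if spread <= tol:  # cannot happen for a connected graph; guard anyway
        raise DualGraphError("degenerate Fiedler vector with zero spread")
    scaled = v * (n - 1) / spread
    x = np.arange(1, n + 1, dtype=float)
    slope, intercept = np.polyfit(x, scaled, 1)
    residuals = scaled - (slope * x + intercept)
    mse = float(np.mean(residuals**2))
    return FiedlerFeatures(
        fiedler_value=lam2,
        s=float(slope),
        e=mse,
        scaled_components=tuple(float(t) for t in scaled),
    )


def rag2d_distance(f1: FiedlerFeatures, f2: FiedlerFeatures) -> float:
    """Euclidean distance between two (s, e) feature points."""
    return math.hypot(f1.s - f2.s, f1.e - f2.e)


def structure_features(
    structure: SecondaryStructure, merge_gap: int = 1
) -> FiedlerFeatures:
    """Convenience composition: structure -> dual graph -> features."""
    return fiedler_features(build_dual_graph(structure, merge_gap))
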