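"""Topological complexity measures of pseudoknotted structures.

Two whole-molecule invariants are computed from the arc diagram:

* **genus** -- the minimum number of handles that must be attached to a
  sphere for the diagram to be drawable without arc crossings.  It is
  obtained combinatorially from the fatgraph (ribbon-graph) picture:
  thicken the backbone and every arc into ribbons and count the
  boundary components ``r`` of the resulting surface; with ``n`` arcs
  on a single backbone the genus is ``g = (n - r + 1) / 2``.

* **pseudoknot order** -- regions (maximal stacks of nested pairs with
  no unpaired nucleotide inside the stack) are layered: layer 0 is a
  maximum crossing-free subset of regions, layer 1 a maximum
  crossing-free subset of the remainder, and so on; the order of the
  structure is the index of the deepest layer.  A pseudoknot-free
  structure has order 0; two mutually crossing regions give order 1.

Both invariants induce a trivial dissimilarity between molecules: the
absolute difference of the values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .io import Pair, SecondaryStructure, arcs_cross

#: largest region conflict graph attacked by exhaustive layering
EXACT_REGION_CAP = 20


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """Maximal stack of consecutively nested pairs (i,j),(i+1,j-1),..."""

    pairs: Tuple[Pair, ...]

    @property
    def span(self) -> Pair:
        """Outermost pair of the stack."""
        return self.pairs[0]

    def crosses(self, other: "Region") -> bool:
        """True iff some pair of self crosses some pair of other.

        For stacked regions it suffices to test the extreme pairs, but
        the regions are tiny so the all-pairs test stays.
        """
        return any(arcs_cross(a, b) for a in self.pairs for b in other.pairs)


def extract_regions(structure: SecondaryStructure) -> List[Region]:
    """Partition the arcs of *structure* into maximal stacked regions.

    A pair ``(i, j)`` extends the region of ``(i-1, j+1)``; a pair with
    no such predecessor opens a new region.  Regions are returned in
    left-endpoint order of their spans.
    """
    pair_set = structure.pairs
    regions: List[Region] = []
    for i, j in structure.sorted_pairs():
        if (i - 1, j + 1) in pair_set:
            continue  # interior of a stack; reached from its opener
        stack = [(i, j)]
        while (stack[-1][0] + 1, stack[-1][1] - 1) in pair_set:
            stack.append((stack[-1][0] + 1, stack[-1][1] - 1))
        regions.append(Region(tuple(stack)))
    regions.sort(key=lambda r: (r.span[0], -r.span[1]))
    return regions


def region_conflict_graph(regions: Sequence[Region]) -> List[Tuple[int, int]]:
    """Edges (index pairs) between regions that cross each other."""
    edges = []
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            if regions[a].crosses(regions[b]):
                edges.append((a, b))
    return edges


# ---------------------------------------------------------------------------
# genus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenusResult:
    """Fatgraph boundary-walk output: 2g = n_arcs - boundary_loops + 1."""

    n_arcs: int
    boundary_loops: int
    genus: int


def genus(structure: SecondaryStructure) -> GenusResult:
    """Genus of *structure* via the fatgraph boundary walk.

    The 2n arc endpoints are placed in backbone order on a circle
    (closing the single backbone).  The boundary components of the
    thickened diagram are the cycles of the permutation ``alpha o tau``
    where ``tau`` swaps the endpoints of each arc and ``alpha`` rotates
    one step along the backbone.  Each endpoint (one side of a ribbon)
    is consumed exactly once; the walk asserts that conservation.
    """
    arcs = structure.sorted_pairs()
    n = len(arcs)
    if n == 0:
        return GenusResult(n_arcs=0, boundary_loops=1, genus=0)
    # rank endpoints 0..2n-1 in backbone order
    endpoints = sorted(p for arc in arcs for p in arc)
    rank = {p: k for k, p in enumerate(endpoints)}
    m = 2 * n
    tau = list(range(m))
    for i, j in arcs:
        tau[rank[i]], tau[rank[j]] = rank[j], rank[i]
    visited = [False] * m
    loops = 0
    consumed = 0
    for start in range(m):
        if visited[start]:
            continue
        loops += 1
        x = start
        while not visited[x]:
            visited[x] = True
            consumed += 1
            x = (tau[x] + 1) % m  # alpha o tau
    assert consumed == m, "boundary walk must consume every ribbon side once"
    g2 = n - loops + 1
    assert g2 % 2 == 0 and g2 >= 0
    return GenusResult(n_arcs=n, boundary_loops=loops, genus=g2 // 2)


# ---------------------------------------------------------------------------
# pseudoknot order
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderAssignment:
    """Layer index per region plus the structure-level order (max layer)."""

    region_orders: Tuple[int, ...]
    structure_order: int
    exact: bool


def _max_independent_set_exact(n: int, adj: List[set]) -> List[int]:
    """Deterministic maximum independent set by branch and bound.

    Among maximum-cardinality sets the lexicographically smallest index
    tuple is returned, which in particular prefers sets containing the
    leftmost-spanning region (index 0).
    """
    best: List[int] = []

    def recurse(candidates: List[int], chosen: List[int]) -> None:
        nonlocal best
        if len(chosen) + len(candidates) < len(best):
            return
        if not candidates:
            if len(chosen) > len(best) or (
                len(chosen) == len(best) and chosen < best
            ):
                best = list(chosen)
            return
        v = candidates[0]
        rest = candidates[1:]
        # include v first: favours lexicographically small sets
        recurse([u for u in rest if u not in adj[v]], chosen + [v])
        recurse(rest, chosen)

    recurse(list(range(n)), [])
    return best


def _max_independent_set_greedy(n: int, adj: List[set]) -> List[int]:
    """First-fit heuristic: scan regions in index order (leftmost span
    first) and keep each one that conflicts with nothing kept so far.

    The result is the lexicographically smallest *maximal* independent
    set; whenever that set also has maximum cardinality it coincides
    with the exact mode's choice.
    """
    chosen: List[int] = []
    blocked: set = set()
    for v in range(n):
        if v not in blocked:
            chosen.append(v)
            blocked |= adj[v]
    return chosen


def pseudoknot_order(
    structure: SecondaryStructure, exact: Optional[bool] = None
) -> OrderAssignment:
    """Layer the region conflict graph and return per-region orders.

    Layers are peeled by repeatedly extracting a crossing-free region
    subset of maximum cardinality; regions in the k-th extracted subset
    receive order k and the structure order is the deepest layer index.

    ``exact=True`` uses exhaustive branch-and-bound (refused above
    ``EXACT_REGION_CAP`` regions); ``exact=False`` a deterministic
    greedy heuristic; ``None`` picks exact when feasible.
    """
    regions = extract_regions(structure)
    n = len(regions)
    adj: List[set] = [set() for _ in range(n)]
    for a, b in region_conflict_graph(regions):
        adj[a].add(b)
        adj[b].add(a)

    if exact is True and n > EXACT_REGION_CAP:
        raise ValueError(
            f"exact layering refused for {n} > {EXACT_REGION_CAP} regions; "
            "use exact=False"
        )
    use_exact = exact if exact is not None else n <= EXACT_REGION_CAP
    mis = _max_independent_set_exact if use_exact else _max_independent_set_greedy

    orders = [-1] * n
    remaining = list(range(n))
    layer = 0
    while remaining:
        sub_index = {v: k for k, v in enumerate(remaining)}
        sub_adj = [
            {sub_index[u] for u in adj[v] if u in sub_index} for v in remaining
        ]
        picked = mis(len(remaining), sub_adj)
        for k in picked:
            orders[remaining[k]] = layer
        remaining = [v for k, v in enumerate(remaining) if k not in set(picked)]
        layer += 1
    structure_order = max(orders) if orders else 0
    return OrderAssignment(
        region_orders=tuple(orders),
        structure_order=structure_order,
        exact=use_exact,
    )


# ---------------------------------------------------------------------------
# induced dissimilarities
# ---------------------------------------------------------------------------

def genus_distance(a: SecondaryStructure, b: SecondaryStructure) -> float:
    """Absolute difference of the genera of two structures."""
    return float(abs(genus(a).genus - genus(b).genus))


def order_distance(
    a: SecondaryStructure, b: SecondaryStructure, exact: Optional[bool] = None
) -> float:
    """Absolute difference of the pseudoknot orders of two structures."""
    return float(
        abs(
            pseudoknot_order(a, exact).structure_order
            - pseudoknot_order(b, exact).structure_order
        )
    )
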