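"""ASPRA distance: algebraic structural trees and ordered tree alignment.

A structure is abstracted into a binary *structural RNA tree* over
three operators -- concatenation, nesting and crossing -- built by
repeatedly selecting the arc with the rightmost paired nucleotide and
classifying its relation to the remaining arcs:

* CROSS(k)  if it crosses k >= 1 remaining arcs (k is part of the label);
* NEST      if the remaining arcs all lie strictly inside it;
* CONCAT    otherwise.

The left child of each internal node is the tree of the remaining
structure, the right child the selected arc as a leaf; the recursion
bottoms out when a single arc is left.  Unpaired nucleotides play no
role: the trees abstract away the primary sequence entirely.

The ASPRA distance between two structures is the minimum-cost
alignment of their trees under a configurable edit scoring scheme,
computed with the ordered tree-alignment dynamic program of Jiang,
Wang and Zhang.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

from .io import SecondaryStructure, arcs_cross

LEAF = "ARC"
CONCAT = "CONCAT"
NEST = "NEST"
CROSS = "CROSS"  # label rendered as ("CROSS", k)

Label = Tuple[str, int]


@dataclass(frozen=True)
class TreeNode:
    """Node of a structural RNA tree.

    ``label`` is ``(operator, crossing_count)``; the count is 0 except
    for CROSS nodes.  Internal nodes have exactly two children in
    (remaining-structure, selected-arc) order; leaves none.
    """

    label: Label
    children: Tuple["TreeNode", ...] = ()

    @property
    def size(self) -> int:
        return 1 + sum(c.size for c in self.children)

    def __str__(self) -> str:  # compact operator-notation dump
        op, k = self.label
        name = f"{op}[{k}]" if op == CROSS else op
        if not self.children:
            return name
        return f"{name}({', '.join(str(c) for c in self.children)})"


#: sentinel for the tree of an arc-less structure
EMPTY_TREE: Optional[TreeNode] = None


def build_structural_tree(structure: SecondaryStructure) -> Optional[TreeNode]:
    """Build the structural RNA tree of *structure*.

    Returns ``None`` (the empty-tree sentinel) for a structure with no
    pairs.  Classification precedence when the rightmost arc relates
    differently to different remaining arcs: crossing wins, then
    nesting, then concatenation.
    """
    arcs = sorted(structure.pairs, key=lambda p: p[1])  # by right endpoint
    if not arcs:
        return EMPTY_TREE

    def rec(upto: int) -> TreeNode:
        # tree over arcs[0..upto]
        sel = arcs[upto]
        if upto == 0:
            return TreeNode((LEAF, 0))
        rest = arcs[:upto]
        k = sum(1 for a in rest if arcs_cross(sel, a))
        if k > 0:
            label: Label = (CROSS, k)
        else:
            lo = min(a[0] for a in rest)
            # sel has the rightmost endpoint, so containment can only
            # run one way: all remaining arcs strictly inside sel
            label = (NEST, 0) if lo > sel[0] else (CONCAT, 0)
        return TreeNode(label, (rec(upto - 1), TreeNode((LEAF, 0))))

    return rec(len(arcs) - 1)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringScheme:
    """Edit costs for tree alignment.

    Defaults are unit costs: replacing a node by an identically
    labelled one is free, any other replacement costs 1 (CROSS labels
    with different crossing counts count as different), and every
    insertion or deletion costs 1.
    """

    replace_mismatch: float = 1.0
    indel: float = 1.0

    def replace(self, a: Label, b: Label) -> float:
        return 0.0 if a == b else self.replace_mismatch

    def delete(self, a: Label) -> float:
        return self.indel

    def insert(self, b: Label) -> float:
        return self.indel


DEFAULT_SCORING = ScoringScheme()


# ---------------------------------------------------------------------------
# ordered tree alignment (Jiang-Wang-Zhang)
# ---------------------------------------------------------------------------

Forest = Tuple[TreeNode, ...]


class _Aligner:
    """Memoised alignment DP over ordered forests.

    Forests are keyed by tuples of node identities; the trees are
    immutable so ``id`` is a stable key within one alignment run.
    """

    def __init__(self, scoring: ScoringScheme):
        self.s = scoring
        self._forest_memo: Dict[Tuple[tuple, tuple], float] = {}
        self._tree_memo: Dict[Tuple[int, int], float] = {}
        self._gap_memo: Dict[int, float] = {}

    def gap(self, f: Forest) -> float:
        """Cost of aligning forest *f* against nothing."""
        total = 0.0
        for t in f:
            key = id(t)
            if key not in self._gap_memo:
                self._gap_memo[key] = self.s.delete(t.label) + self.gap(t.children)
            total += self._gap_memo[key]
        return total

    def tree(self, t: TreeNode, u: TreeNode) -> float:
        key = (id(t), id(u))
        if key in self._tree_memo:
            return self._tree_memo[key]
        best = min(
            self.s.replace(t.label, u.label) + self.forest(t.children, u.children),
            self.s.delete(t.label) + self.forest(t.children, (u,)),
            self.s.insert(u.label) + self.forest((t,), u.children),
        )
        self._tree_memo[key] = best
        return best

    def forest(self, f: Forest, g: Forest) -> float:
        if not f and not g:
            return 0.0
        if not f or not g:
            return self.gap(f or g)
        key = (tuple(id(t) for t in f), tuple(id(t) for t in g))
        if key in self._forest_memo:
            return self._forest_memo[key]
        t, u = f[-1], g[-1]
        options = [self.forest(f[:-1], g[:-1]) + self.tree(t, u)]
        # delete root of t: its children forest aligns with a suffix of g
        for k in range(len(g) + 1):
            options.append(
                self.s.delete(t.label)
                + self.forest(f[:-1], g[:k])
                + self.forest(t.children, g[k:])
            )
        # insert root of u: symmetric
        for k in range(len(f) + 1):
            options.append(
                self.s.insert(u.label)
                + self.forest(f[:k], g[:-1])
                + self.forest(f[k:], u.children)
            )
        best = min(options)
        self._forest_memo[key] = best
        return best


@dataclass(frozen=True)
class AspraDistance:
    value: float


def align_trees(
    t1: Optional[TreeNode],
    t2: Optional[TreeNode],
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> AspraDistance:
    """Minimum alignment cost between two structural trees.

    Either argument may be the empty-tree sentinel ``None``, in which
    case the other tree is paid for entirely with indel costs.
    """
    aligner = _Aligner(scoring)
    f1: Forest = () if t1 is None else (t1,)
    f2: Forest = () if t2 is None else (t2,)
    return AspraDistance(aligner.forest(f1, f2))


def aspra_distance(
    a: SecondaryStructure,
    b: SecondaryStructure,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> AspraDistance:
    """ASPRA distance: align the structural RNA trees of two structures."""
    return align_trees(build_structural_tree(a), build_structural_tree(b), scoring)
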