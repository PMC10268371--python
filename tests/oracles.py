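"""Independent brute-force oracles used by the test suite only."""

from itertools import combinations

from pktaxa import SecondaryStructure
from pktaxa.aspra import ScoringScheme, TreeNode


def brute_crossings(structure: SecondaryStructure):
    """All crossing arc pairs by O(n^2) enumeration of the definition."""
    out = set()
    for a, b in combinations(sorted(structure.pairs), 2):
        (i, j), (k, l) = sorted((a, b))
        if i < k < j < l:
            out.add((min(a, b), max(a, b)))
    return out


def brute_min_alignment(f1, f2, scoring: ScoringScheme) -> float:
    """Minimum alignment cost by exhaustive enumeration of alignment
    forests, built left to right from the definition: the first
    alignment tree's root is a match of the two first roots, a
    deletion covering the first left tree and a prefix of the right
    forest, or an insertion covering the converse.  No memoisation, no
    pruning -- feasible only for tiny trees.
    """
    f1, f2 = tuple(f1), tuple(f2)
    if not f1 and not f2:
        return 0.0
    options = []
    if f1 and f2:
        t, u = f1[0], f2[0]
        options.append(
            scoring.replace(t.label, u.label)
            + brute_min_alignment(t.children, u.children, scoring)
            + brute_min_alignment(f1[1:], f2[1:], scoring)
        )
    if f1:
        t = f1[0]
        for k in range(len(f2) + 1):
            options.append(
                scoring.delete(t.label)
                + brute_min_alignment(t.children, f2[:k], scoring)
                + brute_min_alignment(f1[1:], f2[k:], scoring)
            )
    if f2:
        u = f2[0]
        for k in range(len(f1) + 1):
            options.append(
                scoring.insert(u.label)
                + brute_min_alignment(f1[:k], u.children, scoring)
                + brute_min_alignment(f1[k:], f2[1:], scoring)
            )
    return min(options)


def tree_size(t: TreeNode | None) -> int:
    return 0 if t is None else t.size
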