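"""Reading, writing and validation of RNA secondary structures.

A secondary structure is modelled as an arc diagram: nucleotides
``1..length`` on a horizontal backbone, with each weak (hydrogen) bond
drawn as an arc joining two non-consecutive positions.  Three text
formats are supported, each in a headered and a header-free dialect as
they circulate in rRNA structure databases:

* BPSEQ   -- one ``position base partner`` record per line, partner 0
  meaning unpaired;
* CT      -- six-column connectivity table
  ``index base prev next partner natural-index``;
* dot-bracket-letter -- a single structure line where pseudoknotted
  arcs are encoded with extra bracket families ``[] {} <>`` and letter
  pairs ``A/a, B/b, ...`` (uppercase opens, lowercase closes).

Indexing is 1-based throughout; pairs are stored with ``i < j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Set, Tuple

Pair = Tuple[int, int]

#: bracket families available to the dot-bracket writer, in precedence order
_BRACKET_FAMILIES: list[tuple[str, str]] = (
    [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
    + [(chr(ord("A") + k), chr(ord("a") + k)) for k in range(26)]
)
_OPEN_TO_FAMILY = {o: k for k, (o, _) in enumerate(_BRACKET_FAMILIES)}
_CLOSE_TO_FAMILY = {c: k for k, (_, c) in enumerate(_BRACKET_FAMILIES)}

_VALID_BASES = set("ACGUN")


class StructureError(ValueError):
    """Raised for malformed structure records or invariant violations."""


@dataclass(frozen=True)
class SecondaryStructure:
    """Arc-diagram model of an RNA secondary structure.

    Parameters
    ----------
    length:
        Number of nucleotides on the backbone (>= 1 unless the
        structure is entirely empty).
    pairs:
        Frozen set of 1-based ``(i, j)`` arcs with ``i < j``.
    sequence:
        Optional nucleotide string over ``{A, C, G, U, N}``; downstream
        comparison methods ignore it, so it may be absent.
    """

    length: int
    pairs: FrozenSet[Pair] = frozenset()
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise StructureError(f"negative length {self.length}")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise StructureError(
                    f"sequence length {len(self.sequence)} != {self.length}"
                )
            bad = set(self.sequence) - _VALID_BASES
            if bad:
                raise StructureError(f"invalid bases {sorted(bad)}")
        seen: Set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise StructureError(f"pair ({i}, {j}) out of range 1..{self.length}")
            if j < i + 2:
                raise StructureError(
                    f"pair ({i}, {j}) joins consecutive positions"
                )
            for x in (i, j):
                if x in seen:
                    raise StructureError(f"position {x} appears in multiple pairs")
                seen.add(x)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[Pair]:
        """Pairs sorted by left endpoint (canonical order)."""
        return sorted(self.pairs)

    def partner_array(self) -> list[int]:
        """1-indexed partner table; entry 0 unused, unpaired -> 0."""
        partner = [0] * (self.length + 1)
        for i, j in self.pairs:
            partner[i] = j
            partner[j] = i
        return partner

    def is_pseudoknot_free(self) -> bool:
        return not crossing_pairs(self)


@dataclass(frozen=True)
class CrossingRelation:
    """An unordered pair of arcs that cross: i < k < j < l."""

    pair_a: Pair
    pair_b: Pair

    def __post_init__(self) -> None:
        if self.pair_a > self.pair_b:  # canonical order for set semantics
            object.__setattr__(self, "pair_a", self.pair_b)
            object.__setattr__(self, "pair_b", self.pair_a)


def arcs_cross(a: Pair, b: Pair) -> bool:
    """True iff arcs ``a`` and ``b`` cross (i < k < j < l after ordering)."""
    (i, j), (k, l) = sorted((a, b))
    return i < k < j < l


def crossing_pairs(structure: SecondaryStructure) -> Set[CrossingRelation]:
    """All unordered pairs of crossing arcs of *structure*.

    Sweep over arcs sorted by left endpoint; ``(i,j)`` and ``(k,l)``
    with ``i < k`` cross iff ``k < j < l``.
    """
    out: Set[CrossingRelation] = set()
    arcs = structure.sorted_pairs()
    for a in range(len(arcs)):
        i, j = arcs[a]
        for b in range(a + 1, len(arcs)):
            k, l = arcs[b]
            if k >= j:
                break  # later arcs start at/after j: disjoint, cannot cross
            if j < l:
                out.add(CrossingRelation(arcs[a], arcs[b]))
    return out


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _record_lines(text: str, headered: bool, n_columns: int) -> list[list[str]]:
    """Split *text* into whitespace-separated records.

    In headered mode, leading lines starting with '#', '>' or whose
    first token is not an integer are skipped; the header ends at the
    first record-like line.  In header-free mode every non-blank line
    must be a record.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    records: list[list[str]] = []
    in_header = headered
    for ln in lines:
        stripped = ln.strip()
        toks = stripped.split()
        # a record has exactly the format's column count and a numeric
        # first token; CT headers like "120 title" fail the column test
        is_record = (
            len(toks) == n_columns
            and toks[0].lstrip("-").isdigit()
            and not stripped.startswith(("#", ">"))
        )
        if in_header:
            if not is_record:
                continue
            in_header = False
        if not is_record:
            raise StructureError(f"malformed record line: {stripped!r}")
        records.append(toks)
    return records


def _structure_from_partner_records(
    records: Iterable[Tuple[int, str, int]],
) -> SecondaryStructure:
    """Shared BPSEQ/CT back end: validate records, build the structure."""
    positions: list[int] = []
    partners: dict[int, int] = {}
    bases: list[str] = []
    for pos, base, partner in records:
        positions.append(pos)
        bases.append(base if base in _VALID_BASES else "N")
        partners[pos] = partner
    n = len(positions)
    if positions != list(range(1, n + 1)):
        raise StructureError("positions are not consecutive 1..n")
    pairs: Set[Pair] = set()
    for i, j in partners.items():
        if j == 0:
            continue
        if j == i:
            raise StructureError(f"position {i} paired with itself")
        if abs(j - i) == 1:
            raise StructureError(f"pair ({i}, {j}) joins adjacent positions")
        if not (1 <= j <= n):
            raise StructureError(f"partner {j} of position {i} out of range")
        if partners.get(j) != i:
            raise StructureError(
                f"asymmetric pairing: {i} -> {j} but {j} -> {partners.get(j)}"
            )
        pairs.add((min(i, j), max(i, j)))
    return SecondaryStructure(length=n, pairs=frozenset(pairs),
                              sequence="".join(bases) if n else None)


def parse_bpseq(text: str, headered: bool = True) -> SecondaryStructure:
    """Parse BPSEQ ``position base partner`` records.

    With ``headered=True`` leading comment/header lines are skipped
    (the benchmark's plain dialect); with ``headered=False`` (the
    "-nH" dialect) every non-blank line must be a record.
    """
    records = []
    for toks in _record_lines(text, headered, 3):
        if len(toks) != 3:
            raise StructureError(f"BPSEQ record needs 3 columns: {toks}")
        try:
            records.append((int(toks[0]), toks[1].upper(), int(toks[2])))
        except ValueError as exc:
            raise StructureError(f"non-numeric BPSEQ field in {toks}") from exc
    return _structure_from_partner_records(records)


def parse_ct(text: str, headered: bool = True) -> SecondaryStructure:
    """Parse a 6-column CT connectivity table (single model)."""
    records = []
    for toks in _record_lines(text, headered, 6):
        if len(toks) != 6:
            raise StructureError(f"CT record needs 6 columns: {toks}")
        try:
            records.append((int(toks[0]), toks[1].upper(), int(toks[4])))
        except ValueError as exc:
            raise StructureError(f"non-numeric CT field in {toks}") from exc
    return _structure_from_partner_records(records)


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse dot-bracket-letter notation.

    Accepts an optional '>'-header and an optional sequence line before
    the structure line.  Pairs are reconstructed with one stack per
    bracket family.
    """
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    lines = [ln for ln in lines if not ln.startswith((">", "#"))]
    if not lines:
        raise StructureError("empty dot-bracket input")
    struct_line = lines[-1]
    sequence: Optional[str] = None
    if len(lines) >= 2:
        cand = lines[-2].upper()
        if set(cand) <= _VALID_BASES and len(cand) == len(struct_line):
            sequence = cand
    stacks: dict[int, list[int]] = {}
    pairs: Set[Pair] = set()
    for pos, ch in enumerate(struct_line, start=1):
        if ch == ".":
            continue
        if ch in _OPEN_TO_FAMILY:
            stacks.setdefault(_OPEN_TO_FAMILY[ch], []).append(pos)
        elif ch in _CLOSE_TO_FAMILY:
            fam = _CLOSE_TO_FAMILY[ch]
            if not stacks.get(fam):
                raise StructureError(
                    f"unmatched closing {ch!r} at position {pos}"
                )
            i = stacks[fam].pop()
            pairs.add((i, pos))
        else:
            raise StructureError(f"unknown character {ch!r} at position {pos}")
    for fam, stack in stacks.items():
        if stack:
            o = _BRACKET_FAMILIES[fam][0]
            raise StructureError(f"unbalanced family {o!r}: {len(stack)} open")
    return SecondaryStructure(length=len(struct_line), pairs=frozenset(pairs),
                              sequence=sequence)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _sequence_of(structure: SecondaryStructure) -> str:
    return structure.sequence or "N" * structure.length


def write_bpseq(structure: SecondaryStructure, headered: bool = True) -> str:
    seq = _sequence_of(structure)
    partner = structure.partner_array()
    lines = [] if not headered else ["# BPSEQ written by pktaxa"]
    for i in range(1, structure.length + 1):
        lines.append(f"{i} {seq[i - 1]} {partner[i]}")
    return "\n".join(lines) + "\n"


def write_ct(structure: SecondaryStructure, headered: bool = True) -> str:
    seq = _sequence_of(structure)
    partner = structure.partner_array()
    n = structure.length
    lines = [] if not headered else [f"{n} pktaxa structure"]
    for i in range(1, n + 1):
        nxt = i + 1 if i < n else 0
        lines.append(f"{i} {seq[i - 1]} {i - 1} {nxt} {partner[i]} {i}")
    return "\n".join(lines) + "\n"


def assign_bracket_families(structure: SecondaryStructure) -> dict[Pair, int]:
    """Greedy first-fit assignment of arcs to non-crossing bracket families.

    Arcs are visited in left-endpoint order; each goes to the first
    family none of whose members it crosses.
    """
    families: list[list[Pair]] = []
    assignment: dict[Pair, int] = {}
    for arc in structure.sorted_pairs():
        for k, members in enumerate(families):
            if not any(arcs_cross(arc, m) for m in members):
                members.append(arc)
                assignment[arc] = k
                break
        else:
            if len(families) >= len(_BRACKET_FAMILIES):
                raise StructureError(
                    "crossing complexity exceeds available bracket families"
                )
            families.append([arc])
            assignment[arc] = len(families) - 1
    return assignment


def write_dotbracket(structure: SecondaryStructure, headered: bool = True) -> str:
    assignment = assign_bracket_families(structure)
    chars = ["."] * structure.length
    for (i, j), fam in assignment.items():
        o, c = _BRACKET_FAMILIES[fam]
        chars[i - 1] = o
        chars[j - 1] = c
    line = "".join(chars)
    if headered:
        return f">pktaxa structure\n{_sequence_of(structure)}\n{line}\n"
    return line + "\n"
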