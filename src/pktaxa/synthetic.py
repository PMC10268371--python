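"""Seeded generators of rRNA-like structures and planted-partition data.

Everything downstream of the parsers can be exercised without the
external rRNA benchmark: this module fabricates

* pseudoknot-free structures (random ordered forests of stacked
  helices with unpaired strands between them),
* pseudoknotted structures with an exact number of crossing region
  pairs (each crossing motif is a pair of helices interleaved as
  a..b..a'..b' in its own coordinate window),
* mutually crossing region cliques (m regions that pairwise cross,
  giving pseudoknot order m - 1),
* labelled molecule sets whose taxa differ in crossing complexity, and
* planted-block distance matrices with configurable within- and
  between-taxon dissimilarity levels.

All generators are pure functions of (seed, call-site tag): each draws
from its own stream, so adding a generator never shifts the output of
another.  Helix and strand dimensions default to small rRNA-like
values; strands between helices are kept at two or more nucleotides so
the dual-graph representation of every generated structure is
connected.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

from .clustering import DistanceMatrix
from .io import SecondaryStructure, parse_dotbracket, _BRACKET_FAMILIES


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study conditions.

    Ranges are inclusive.  ``within`` / ``between`` give the mean and
    spread (normal s.d.) of planted-block dissimilarities; a separated
    regime has ``between_mean`` well above ``within_mean``.
    """

    seed: int = 0
    n_molecules: int = 30
    n_taxa: int = 3
    helix_count: Tuple[int, int] = (3, 6)
    helix_length: Tuple[int, int] = (2, 5)
    crossing_count: int = 1
    within_mean: float = 0.1
    within_spread: float = 0.02
    between_mean: float = 1.0
    between_spread: float = 0.05

    def __post_init__(self) -> None:
        for name in ("helix_count", "helix_length"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid {name} range ({lo}, {hi})")
        if self.n_taxa > self.n_molecules:
            raise ValueError("n_taxa exceeds n_molecules")
        if self.crossing_count < 0:
            raise ValueError("negative crossing_count")


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Independent stream per (seed, call-site tag)."""
    key = zlib.crc32(tag.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# structure generators
# ---------------------------------------------------------------------------

def _gap(rng: np.random.Generator, lo: int = 2, hi: int = 5) -> str:
    return "." * int(rng.integers(lo, hi + 1))


def _loop(rng: np.random.Generator) -> str:
    return "." * int(rng.integers(3, 7))


def _nested_forest(rng: np.random.Generator, nh: int, cfg: GeneratorConfig) -> str:
    """Dot-bracket of a random ordered forest with *nh* helices."""
    if nh == 0:
        return ""
    k = int(rng.integers(1, nh + 1))  # helices in the first tree
    return (
        _nested_tree(rng, k, cfg)
        + (_gap(rng) + _nested_forest(rng, nh - k, cfg) if nh > k else "")
    )


def _nested_tree(rng: np.random.Generator, k: int, cfg: GeneratorConfig) -> str:
    lo, hi = cfg.helix_length
    length = int(rng.integers(lo, hi + 1))
    if k == 1:
        inner = _loop(rng)
    else:
        inner = _gap(rng) + _nested_forest(rng, k - 1, cfg) + _gap(rng)
    return "(" * length + inner + ")" * length


def gen_nested_structure(config: GeneratorConfig) -> SecondaryStructure:
    """A random pseudoknot-free structure (crossing_pairs is empty)."""
    rng = _rng(config.seed, "nested")
    nh = int(rng.integers(config.helix_count[0], config.helix_count[1] + 1))
    db = _gap(rng, 0, 3) + _nested_forest(rng, nh, cfg=config) + _gap(rng, 0, 3)
    return parse_dotbracket(db)


def _crossing_motif(rng: np.random.Generator, cfg: GeneratorConfig,
                    family: int) -> str:
    """Two interleaved helices a..b..a'..b': one crossing region pair."""
    lo, hi = cfg.helix_length
    la = int(rng.integers(lo, hi + 1))
    lb = int(rng.integers(lo, hi + 1))
    o, c = _BRACKET_FAMILIES[family]
    return (
        "(" * la + _gap(rng) + o * lb + _gap(rng)
        + ")" * la + _gap(rng) + c * lb
    )


def gen_pseudoknotted_structure(config: GeneratorConfig) -> SecondaryStructure:
    """Structure with exactly ``config.crossing_count`` crossing region pairs.

    Crossing motifs occupy disjoint coordinate windows separated by
    unpaired strands, concatenated with a nested sub-forest, so the
    region conflict graph is a perfect matching of
    ``crossing_count`` edges and the pseudoknot order is 1.
    A zero crossing count routes to the nested generator.
    """
    if config.crossing_count == 0:
        return gen_nested_structure(config)
    rng = _rng(config.seed, "pseudoknotted")
    parts = [
        _crossing_motif(rng, config, family=1) for _ in range(config.crossing_count)
    ]
    nh = int(rng.integers(config.helix_count[0], config.helix_count[1] + 1))
    parts.append(_nested_forest(rng, nh, config))
    db = _gap(rng).join(parts)
    return parse_dotbracket(db)


def gen_mutually_crossing_structure(
    m: int, config: GeneratorConfig
) -> SecondaryStructure:
    """*m* pairwise-crossing regions: opens 1..m then closes 1..m.

    The region conflict graph is the complete graph on m vertices, so
    the pseudoknot order is m - 1 (m = 1 gives a plain hairpin).
    """
    if m < 1:
        raise ValueError("need at least one region")
    rng = _rng(config.seed, f"clique{m}")
    lo, hi = config.helix_length
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(m)]
    opens = _gap(rng).join(
        _BRACKET_FAMILIES[k][0] * lengths[k] for k in range(m)
    )
    closes = _gap(rng).join(
        _BRACKET_FAMILIES[k][1] * lengths[k] for k in range(m)
    )
    return parse_dotbracket(opens + _gap(rng) + closes)


# ---------------------------------------------------------------------------
# labelled molecule sets
# ---------------------------------------------------------------------------

def gen_labeled_set(
    config: GeneratorConfig,
) -> Tuple[List[str], List[str], List[SecondaryStructure]]:
    """(ids, taxon labels, structures) with taxon-specific complexity.

    Taxon ``T<t>`` gets structures whose crossing clique size is
    ``t + 1`` (taxon T0 is pseudoknot-free), concatenated with a
    per-molecule random nested part, so topology-based methods see
    systematic between-taxon differences.
    """
    rng = _rng(config.seed, "labeled_set")
    ids, taxa, structures = [], [], []
    for i in range(config.n_molecules):
        t = i % config.n_taxa
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub = replace(config, seed=sub_seed)
        if t == 0:
            s = gen_nested_structure(sub)
        else:
            clique = gen_mutually_crossing_structure(t + 1, sub)
            tail = gen_nested_structure(sub)
            s = concatenate(clique, tail, gap=3)
        ids.append(f"mol{i:03d}")
        taxa.append(f"T{t}")
        structures.append(s)
    return ids, taxa, structures


def concatenate(
    a: SecondaryStructure, b: SecondaryStructure, gap: int = 3
) -> SecondaryStructure:
    """Join two structures on disjoint backbone intervals."""
    offset = a.length + gap
    pairs = set(a.pairs) | {(i + offset, j + offset) for i, j in b.pairs}
    seq = None
    if a.sequence and b.sequence:
        seq = a.sequence + "N" * gap + b.sequence
    return SecondaryStructure(
        length=a.length + gap + b.length, pairs=frozenset(pairs), sequence=seq
    )


# ---------------------------------------------------------------------------
# planted-partition distance matrices
# ---------------------------------------------------------------------------

def gen_planted_partition(
    config: GeneratorConfig,
) -> Tuple[DistanceMatrix, List[str]]:
    """Symmetric zero-diagonal matrix with planted taxon blocks.

    Within-block entries are drawn around ``within_mean``,
    between-block entries around ``between_mean``; negative draws are
    clamped to 0.  Labels record the planted taxon of each molecule.
    """
    rng = _rng(config.seed, "planted_partition")
    n = config.n_molecules
    labels = [f"T{i % config.n_taxa}" for i in range(n)]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                d = rng.normal(config.within_mean, config.within_spread)
            else:
                d = rng.normal(config.between_mean, config.between_spread)
            values[i, j] = values[j, i] = max(0.0, float(d))
    ids = [f"mol{i:03d}" for i in range(n)]
    return DistanceMatrix(ids=tuple(ids), values=values), labels
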