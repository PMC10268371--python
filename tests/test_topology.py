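import numpy as np
import pytest

from pktaxa import (
    GeneratorConfig,
    SecondaryStructure,
    concatenate,
    crossing_pairs,
    extract_regions,
    gen_mutually_crossing_structure,
    gen_nested_structure,
    gen_pseudoknotted_structure,
    genus,
    genus_distance,
    order_distance,
    parse_dotbracket,
    pseudoknot_order,
)
from pktaxa.topology import (
    _max_independent_set_exact,
    _max_independent_set_greedy,
    region_conflict_graph,
)
from conftest import random_structure


class TestRegions:
    def test_single_stack(self):
        regions = extract_regions(parse_dotbracket("((..))"))
        assert len(regions) == 1
        assert regions[0].pairs == ((1, 6), (2, 5))

    def test_bulge_splits_stacks(self):
        regions = extract_regions(parse_dotbracket("((.((..))))"))
        assert [r.pairs for r in regions] == [
            ((1, 11), (2, 10)),
            ((4, 9), (5, 8)),
        ]

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_and_maximality(self, seed):
        rng = np.random.default_rng(seed)
        s = random_structure(rng, length=50, n_pairs=12)
        regions = extract_regions(s)
        covered = [p for r in regions for p in r.pairs]
        assert sorted(covered) == s.sorted_pairs()  # exactly one region each
        for r in regions:  # maximal: stack cannot extend either way
            i, j = r.pairs[0]
            assert (i - 1, j + 1) not in s.pairs
            i, j = r.pairs[-1]
            assert (i + 1, j - 1) not in s.pairs


class TestGenus:
    def test_nested_structures_have_genus_zero(self):
        for seed in range(10):
            s = gen_nested_structure(GeneratorConfig(seed=seed))
            assert genus(s).genus == 0

    def test_minimal_crossing_diagram(self):
        s = SecondaryStructure(length=4, pairs=frozenset({(1, 3), (2, 4)}))
        res = genus(s)
        assert (res.n_arcs, res.boundary_loops, res.genus) == (2, 1, 1)

    def test_euler_relation(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = genus(random_structure(rng, length=40, n_pairs=10))
            assert 2 * res.genus == res.n_arcs - res.boundary_loops + 1

    def test_zero_iff_pseudoknot_free(self):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            s = random_structure(rng, length=30, n_pairs=rng.integers(0, 10))
            assert (genus(s).genus == 0) == (not crossing_pairs(s))

    def test_additive_under_concatenation(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = random_structure(rng, length=30, n_pairs=8)
            b = random_structure(rng, length=30, n_pairs=8)
            assert (
                genus(concatenate(a, b)).genus
                == genus(a).genus + genus(b).genus
            )

    def test_stacking_does_not_change_genus(self):
        # doubling every arc into a 2-stack preserves the invariant
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = random_structure(rng, length=60, n_pairs=8)
            thick = {(2 * i - 1, 2 * j) for i, j in s.pairs}
            thick |= {(2 * i, 2 * j - 1) for i, j in s.pairs}
            doubled = SecondaryStructure(
                length=2 * s.length, pairs=frozenset(thick)
            )
            assert genus(doubled).genus == genus(s).genus

    def test_empty_structure(self):
        assert genus(SecondaryStructure(length=0)).genus == 0


class TestPseudoknotOrder:
    def test_nested_is_order_zero(self):
        for seed in range(10):
            s = gen_nested_structure(GeneratorConfig(seed=seed))
            assert pseudoknot_order(s).structure_order == 0

    def test_two_crossing_regions_order_one(self):
        s = SecondaryStructure(
            length=15, pairs=frozenset({(1, 10), (2, 9), (5, 15), (6, 14)})
        )
        oa = pseudoknot_order(s, exact=True)
        assert oa.structure_order == 1
        assert sorted(oa.region_orders) == [0, 1]

    @pytest.mark.parametrize("m,expected", [(1, 0), (2, 1), (3, 2), (4, 3)])
    def test_mutually_crossing_clique(self, m, expected, base_config):
        s = gen_mutually_crossing_structure(m, base_config)
        assert pseudoknot_order(s, exact=True).structure_order == expected

    def test_order_zero_iff_conflict_graph_edgeless(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            s = random_structure(rng, length=40, n_pairs=10)
            edges = region_conflict_graph(extract_regions(s))
            assert (pseudoknot_order(s).structure_order == 0) == (not edges)

    def test_region_order_invariants(self):
        # regions of one layer never cross; each region of layer m > 0
        # crosses some region of layer m - 1
        for seed in range(30):
            rng = np.random.default_rng(seed)
            s = random_structure(rng, length=40, n_pairs=12)
            regions = extract_regions(s)
            oa = pseudoknot_order(s, exact=True)
            for a, b in region_conflict_graph(regions):
                assert oa.region_orders[a] != oa.region_orders[b]
            for k, r in enumerate(regions):
                m = oa.region_orders[k]
                if m > 0:
                    assert any(
                        oa.region_orders[j] == m - 1 and regions[k].crosses(regions[j])
                        for j in range(len(regions))
                    )

    def test_greedy_matches_exact_on_small_structures(self):
        for seed in range(40):
            rng = np.random.default_rng(seed)
            s = random_structure(rng, length=30, n_pairs=rng.integers(2, 10))
            if len(extract_regions(s)) > 10:
                continue
            assert (
                pseudoknot_order(s, exact=True).structure_order
                == pseudoknot_order(s, exact=False).structure_order
            )

    def test_exact_mode_cap(self):
        cfg = GeneratorConfig(seed=1, helix_length=(1, 1))
        s = gen_mutually_crossing_structure(21, cfg)
        with pytest.raises(ValueError):
            pseudoknot_order(s, exact=True)
        assert pseudoknot_order(s).structure_order == 20  # auto falls back


class TestIndependentSets:
    def test_exact_on_five_cycle(self):
        adj = [set() for _ in range(5)]
        for a, b in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]:
            adj[a].add(b)
            adj[b].add(a)
        assert _max_independent_set_exact(5, adj) == [0, 2]

    def test_greedy_is_independent(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = 12
            adj = [set() for _ in range(n)]
            for a in range(n):
                for b in range(a + 1, n):
                    if rng.random() < 0.3:
                        adj[a].add(b)
                        adj[b].add(a)
            picked = _max_independent_set_greedy(n, adj)
            assert all(b not in adj[a] for a in picked for b in picked)


class TestDistances:
    def test_identity_and_symmetry(self, base_config):
        a = gen_nested_structure(base_config)
        b = gen_pseudoknotted_structure(base_config)
        assert genus_distance(a, a) == 0.0
        assert genus_distance(a, b) == genus_distance(b, a) == 1.0
        assert order_distance(a, b) == order_distance(b, a) == 1.0

    def test_order_distance_between_orders(self, base_config):
        nested = gen_nested_structure(base_config)
        order2 = gen_mutually_crossing_structure(3, base_config)
        assert order_distance(nested, order2) == 2.0
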