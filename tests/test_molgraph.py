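"""Molecular-graph construction, shapes, isomorphism and canonical keys."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    brute_force_embeddings,
    brute_force_isomorphic,
    brute_force_pattern_automorphisms,
)
from rxntemplates import fixtures as fx
from rxntemplates.molgraph import (
    Fragment,
    GraphError,
    MolecularGraph,
    assign_shapes,
    build_graph,
    canonical_key,
    connected_components,
    is_isomorphic,
    subgraph_embeddings,
)


class TestBuildGraph:
    def test_ethylene_oxide_connectivity(self):
        g = fx.ethylene_oxide()
        assert g.n_atoms == 7 and len(g.bonds) == 7
        assert g.elements[:3] == ("O", "C", "C")
        assert g.charge == 0

    def test_single_atom_hydride(self):
        g = build_graph(["H"], [], charge=-1)
        assert g.n_atoms == 1 and not g.bonds and g.charge == -1
        assert g.shapes == ("isolated",)

    @pytest.mark.parametrize("bonds,message", [
        ([(0, 0)], "self-loop"),
        ([(0, 1), (1, 0)], "duplicate"),
        ([(0, 9)], "missing atom"),
    ])
    def test_invalid_bonds_rejected(self, bonds, message):
        with pytest.raises(GraphError, match=message):
            build_graph(["C", "O"], bonds)

    def test_invalid_element_rejected(self):
        with pytest.raises(GraphError, match="Xx"):
            build_graph(["Xx"], [])

    def test_mass_is_standard_weight_sum(self):
        # C2H4O: 2*12.011 + 4*1.008 + 15.999
        assert fx.ethylene_oxide().mass == pytest.approx(44.053, abs=1e-3)

    def test_formal_charges_must_sum_to_total(self):
        with pytest.raises(GraphError, match="formal charges"):
            build_graph(["O", "H"], [(0, 1)], charge=-1,
                        formal_charges=[0, 0])

    def test_default_charge_placement_on_valence_deficient_atom(self):
        g = fx.ethoxide()
        assert g.formal_charges[0] == -1  # the terminal O


class TestShapes:
    @pytest.mark.parametrize("element,degree,shape", [
        ("C", 4, "tetrahedron"),
        ("O", 2, "bent"),
        ("C", 3, "trigonal planar"),
        ("Cl", 1, "terminal"),
    ])
    def test_lookup_table(self, element, degree, shape):
        elements = [element] + ["H"] * degree
        g = build_graph(elements, [(0, i) for i in range(1, degree + 1)])
        assert g.shapes[0] == shape

    def test_high_degree_falls_back_to_other(self):
        g = build_graph(["S"] + ["F"] * 6, [(0, i) for i in range(1, 7)])
        assert g.shapes[0] == "other(6)"

    def test_idempotent(self):
        g = fx.propylene_oxide()
        assert assign_shapes(g) == assign_shapes(assign_shapes(g))

    def test_linear_flag(self):
        g = build_graph(["C", "C", "C"], [(0, 1), (1, 2)], linear_atoms=[1])
        assert g.shapes[1] == "linear"


class TestConnectedComponents:
    def test_two_molecule_union_splits(self):
        # methoxide + ethylene oxide sharing one atom list, no cross bonds
        union = build_graph(
            ["O", "C", "H", "H", "H", "O", "C", "C", "H", "H", "H", "H"],
            [(0, 1), (1, 2), (1, 3), (1, 4),
             (5, 6), (5, 7), (6, 7), (6, 8), (6, 9), (7, 10), (7, 11)],
            charge=-1, formal_charges=[-1] + [0] * 11)
        comps = connected_components(union)
        assert len(comps) == 2
        assert sorted(c.charge for c in comps) == [-1, 0]

    def test_single_molecule_identity(self):
        g = fx.ethylene_oxide()
        (comp,) = connected_components(g)
        assert comp.bonds == g.bonds and comp.elements == g.elements

    def test_empty_graph(self):
        empty = MolecularGraph(elements=(), bonds=frozenset())
        assert connected_components(empty) == []

    def test_caller_supplied_charges(self):
        union = build_graph(["Cl", "Br"], [], charge=-2,
                            formal_charges=[-1, -1])
        comps = connected_components(union, charges=[0, -2])
        assert [c.charge for c in comps] == [0, -2]


def _relabel(g, seed):
    rng = random.Random(seed)
    perm = list(range(g.n_atoms))
    rng.shuffle(perm)
    return fx.permute_graph(g, perm)


class TestIsomorphism:
    def test_relabeling_invariance(self):
        g = fx.ethylene_oxide()
        assert is_isomorphic(g, _relabel(g, 3))

    def test_constitutional_isomers_differ(self):
        # acetaldehyde: same formula C2H4O as ethylene oxide
        acetaldehyde = fx.hydride_abstraction().rhs[0]
        eo = fx.ethylene_oxide()
        assert not is_isomorphic(eo, acetaldehyde)
        assert not brute_force_isomorphic(eo, acetaldehyde)

    def test_enantiomeric_descriptors_differ(self):
        base = fx.propylene_oxide()
        a = base.with_stereo(["A" if i == 2 else None
                              for i in range(base.n_atoms)])
        b = base.with_stereo(["B" if i == 2 else None
                              for i in range(base.n_atoms)])
        assert not is_isomorphic(a, b)
        assert is_isomorphic(a, _relabel(a, 11))
        assert canonical_key(a) != canonical_key(b)

    def test_charge_enters_identity(self):
        neutral = build_graph(["Cl"], [])
        anion = build_graph(["Cl"], [], charge=-1)
        assert not is_isomorphic(neutral, anion)
        assert canonical_key(neutral) != canonical_key(anion)


class TestCanonicalKey:
    def test_relabeled_copies_share_keys(self):
        g = fx.cyclopentadiene()
        for seed in range(5):
            assert canonical_key(_relabel(g, seed)) == canonical_key(g)

    def test_distinct_compounds_get_distinct_keys(self):
        graphs = [fx.ethylene_oxide(), fx.ethoxide(), fx.propylene_oxide(),
                  fx.butadiene(), fx.ethylene(), fx.cyclopentadiene(),
                  fx.hydride_abstraction().rhs[0]]
        keys = {canonical_key(g) for g in graphs}
        assert len(keys) == len(graphs)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_key_equality_is_relabeling_invariant(self, seed):
        rng = random.Random(seed)
        g = fx.random_molecule(rng, n_atoms=rng.randint(2, 10),
                               extra_edges=rng.randint(0, 3))
        assert canonical_key(_relabel(g, seed + 1)) == canonical_key(g)
        assert is_isomorphic(g, _relabel(g, seed + 2))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_key_equivalence_matches_brute_force(self, seed):
        """Equal keys exactly when brute-force permutation search succeeds."""
        rng = random.Random(seed)
        n = rng.randint(2, 6)
        g1 = fx.random_molecule(rng, n_atoms=n, extra_edges=rng.randint(0, 2))
        g2 = fx.random_molecule(rng, n_atoms=n, extra_edges=rng.randint(0, 2))
        same_key = canonical_key(g1) == canonical_key(g2)
        assert same_key == brute_force_isomorphic(g1, g2)
        assert same_key == is_isomorphic(g1, g2)


class TestSubgraphEmbeddings:
    def test_single_bent_oxygen_in_epoxide(self):
        pattern = Fragment(("O",), (frozenset({"bent"}),))
        assert len(subgraph_embeddings(pattern, fx.ethylene_oxide())) == 1

    def test_two_tetrahedral_carbons_in_epoxide(self):
        pattern = Fragment(("C",), (frozenset({"tetrahedron"}),))
        assert len(subgraph_embeddings(pattern, fx.ethylene_oxide())) == 2

    def test_pattern_larger_than_host_is_empty(self):
        pattern = Fragment(("C",) * 9,
                           (frozenset({"tetrahedron"}),) * 9,
                           frozenset((i, i + 1) for i in range(8)))
        assert subgraph_embeddings(pattern, fx.ethylene_oxide()) == []

    @pytest.mark.parametrize("host_name", [
        "ethylene_oxide", "ethoxide", "propylene_oxide", "ethylene",
    ])
    @pytest.mark.parametrize("pattern", [
        Fragment(("C",), (frozenset({"tetrahedron"}),)),
        Fragment(("O", "C"), (frozenset({"bent"}), frozenset({"tetrahedron"})),
                 frozenset({(0, 1)})),
        Fragment(("C", "C"),
                 (frozenset({"tetrahedron", "trigonal planar"}),) * 2,
                 frozenset({(0, 1)})),
    ])
    def test_matcher_equals_exhaustive_enumeration(self, host_name, pattern):
        """Embeddings agree with brute-force injective-map search up to
        pattern automorphisms."""
        host = getattr(fx, host_name)()
        got = {tuple(e.as_dict[p] for p in range(pattern.n_atoms))
               for e in subgraph_embeddings(pattern, host)}
        expected_all = brute_force_embeddings(pattern, host)
        autos = brute_force_pattern_automorphisms(pattern)
        # collapse the oracle's results the same way, independently
        expected = {min(tuple(c[a[p]] for p in range(pattern.n_atoms))
                        for a in autos)
                    for c in expected_all}
        got_reps = {min(tuple(c[a[p]] for p in range(pattern.n_atoms))
                        for a in autos) for c in got}
        assert got_reps == expected
        assert got <= expected_all
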