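"""Template extraction, template-graph identity, merging, GED, spectra."""

import random
import warnings

import pytest

from rxntemplates import fixtures as fx
from rxntemplates.reactions import reverse
from rxntemplates.templates import (
    ReactionTemplate,
    TemplateAtom,
    TemplateError,
    TemplateLibrary,
    TemplateSide,
    barrier_spectrum,
    build_template_graph,
    deduplicate,
    extract_template,
    ged_matrix,
    merge,
    reverse_template,
    template_ged,
    template_to_dot,
    templates_isomorphic,
)


def tiny_transfer_template(element: str) -> ReactionTemplate:
    """A minimal one-atom-per-side template (donor atom only)."""
    side = TemplateSide(
        atoms=(TemplateAtom(element, frozenset({"terminal"})),),
        bonds=frozenset(), fragment_of=(0,), molecule_of_fragment=(0,),
        formal_charges=(0,))
    return ReactionTemplate(side_a=side, side_b=side, cross_map=(0,),
                            barriers_ab=(50.0,))


class TestExtraction:
    def test_diels_alder_fragment_structure(self, da_template):
        t = da_template
        # reactant side: two 1-atom C fragments (diene) + one C-C fragment
        assert t.side_a.n_atoms == 4
        assert t.side_a.n_fragments == 3
        assert t.side_a.n_molecules == 2
        sizes = sorted(len(t.side_a.fragment_atoms(f))
                       for f in range(t.side_a.n_fragments))
        assert sizes == [1, 1, 2]
        # product side: a single connected 4-atom fragment
        assert t.side_b.n_atoms == 4
        assert t.side_b.n_fragments == 1
        assert t.side_b.n_molecules == 1
        assert len(t.formed) == 2 and len(t.broken) == 0

    def test_sn2_fragment_structure(self, sn2_template):
        t = sn2_template
        assert t.side_a.n_atoms == t.side_b.n_atoms == 3
        assert t.side_a.n_molecules == 2  # nucleophile + substrate
        sizes = sorted(len(t.side_a.fragment_atoms(f))
                       for f in range(t.side_a.n_fragments))
        assert sizes == [1, 2]
        assert len(t.formed) == 1 and len(t.broken) == 1

    def test_elongation_matches_hand_built_template(self, peo):
        assert templates_isomorphic(peo.template,
                                    fx.hand_built_elongation_template())

    def test_spectator_molecules_dropped(self):
        # SN2 template keeps 2 molecules per side although hydrogens of the
        # substrate never react
        t = extract_template(fx.sn2())
        elements = sorted(a.element for a in t.side_a.atoms)
        assert elements == ["Br", "C", "Cl"]

    def test_observed_shapes_recorded(self, peo):
        shapes = {a.element: a.allowed_shapes for a in peo.template.side_a.atoms}
        assert shapes["C"] == frozenset({"tetrahedron"})

    def test_degenerate_reaction_rejected(self):
        from rxntemplates.reactions import DegenerateReactionError, MappedReaction
        g = fx.ethylene_oxide()
        r = MappedReaction(lhs=(g,), rhs=(g,), atom_map=tuple(range(7)))
        with pytest.raises(DegenerateReactionError):
            extract_template(r)

    def test_barriers_attached(self, peo):
        assert peo.template.barriers_ab == (72.0,)
        assert peo.template.barriers_ba == (102.0,)


class TestTemplateGraph:
    def test_diels_alder_node_counts(self, da_template):
        g = build_template_graph(da_template)
        kinds = {}
        for _, attrs in g.nodes(data=True):
            kinds[attrs["kind"]] = kinds.get(attrs["kind"], 0) + 1
        assert kinds == {"atom": 8, "fragment": 4, "molecule": 3}
        map_edges = [1 for *_, a in g.edges(data=True) if a["kind"] == "map"]
        assert len(map_edges) == 4

    def test_smallest_legal_graph(self):
        g = build_template_graph(tiny_transfer_template("H"))
        assert g.number_of_nodes() == 6  # atom+fragment+molecule per side
        map_edges = [1 for *_, a in g.edges(data=True) if a["kind"] == "map"]
        assert len(map_edges) == 1

    def test_build_is_deterministic(self, sn2_template):
        import networkx as nx
        g1 = build_template_graph(sn2_template)
        g2 = build_template_graph(sn2_template)
        assert nx.utils.graphs_equal(g1, g2)

    def test_dot_export_carries_edge_classes(self, sn2_template):
        dot = template_to_dot(sn2_template)
        for token in ("color=red", "color=green", "style=dashed",
                      "style=dotted", "shape=ellipse", "shape=box"):
            assert token in dot


class TestIsomorphism:
    def test_relabeled_extraction_is_identical(self, peo):
        for seed in range(5):
            t2 = extract_template(fx.shuffled_reaction(peo.reaction, seed))
            assert templates_isomorphic(peo.template, t2)

    def test_different_reactions_differ(self, da_template, sn2_template):
        assert not templates_isomorphic(da_template, sn2_template)

    def test_chain_elongation_is_length_independent(self, peo):
        """The template extracted from n=0->1 equals the one from n=1->2."""
        from rxntemplates.matching import apply_match, match_template
        n1 = peo.reaction.rhs[0]
        (m,) = [m for m in match_template(peo.template,
                                          (n1, fx.ethylene_oxide()))
                if m.side == "a"]
        (applied,) = apply_match(m)
        t2 = extract_template(applied.reaction)
        assert templates_isomorphic(peo.template, t2, shape_strict=False)

    def test_reverse_reading_is_the_same_template(self, peo):
        t_rev = extract_template(reverse(peo.reaction))
        assert templates_isomorphic(peo.template, t_rev)

    def test_shape_strictness_distinguishes(self, peo):
        widened = merge(peo.template, peo.template)
        relaxed = ReactionTemplate(
            side_a=TemplateSide(
                atoms=tuple(TemplateAtom(a.element,
                                         a.allowed_shapes | {"bent"})
                            for a in widened.side_a.atoms),
                bonds=widened.side_a.bonds,
                fragment_of=widened.side_a.fragment_of,
                molecule_of_fragment=widened.side_a.molecule_of_fragment,
                formal_charges=widened.side_a.formal_charges),
            side_b=widened.side_b, cross_map=widened.cross_map)
        assert not templates_isomorphic(peo.template, relaxed,
                                        shape_strict=True)
        assert templates_isomorphic(peo.template, relaxed,
                                    shape_strict=False)


class TestMerge:
    def test_self_merge_doubles_occurrence(self, peo):
        m = merge(peo.template, peo.template)
        assert m.occurrence_count == 2
        assert templates_isomorphic(m, peo.template, shape_strict=False)

    def test_barrier_lists_concatenate(self, peo):
        t1 = peo.template
        t2 = extract_template(fx.shuffled_reaction(peo.reaction, 1))
        t2 = ReactionTemplate(side_a=t2.side_a, side_b=t2.side_b,
                              cross_map=t2.cross_map, barriers_ab=(68.0,),
                              barriers_ba=(95.0,))
        m = merge(t1, t2)
        assert sorted(m.barriers_ab) == [68.0, 72.0]
        assert min(m.barriers_ab) == 68.0

    def test_reversed_duplicate_lands_in_opposite_direction(self, peo):
        t_rev = extract_template(reverse(peo.reaction))
        assert t_rev.barriers_ab == (102.0,)
        m = merge(peo.template, t_rev)
        assert sorted(m.barriers_ab) == [72.0, 72.0]
        assert sorted(m.barriers_ba) == [102.0, 102.0]

    def test_min_barrier_never_increases(self, peo, sn2_template):
        t2 = extract_template(fx.shuffled_reaction(peo.reaction, 7))
        m = merge(peo.template, t2)
        assert min(m.barriers_ab) <= min(peo.template.barriers_ab)

    def test_non_duplicates_rejected(self, da_template, sn2_template):
        with pytest.raises(TemplateError):
            merge(da_template, sn2_template)


class TestDeduplicate:
    def test_relabeled_copy_collapses(self, peo, sn2_template):
        t2 = extract_template(fx.shuffled_reaction(peo.reaction, 2))
        lib = deduplicate([peo.template, t2, sn2_template])
        assert len(lib) == 2

    def test_empty(self):
        assert len(deduplicate([])) == 0

    def test_all_chain_elongations_collapse(self, peo):
        """Every elongation step of a short oligomer network is one entry."""
        from rxntemplates.matching import apply_match, match_template
        reactions = [peo.reaction]
        chain = peo.reaction.rhs[0]
        for _ in range(2):
            (m,) = [m for m in match_template(peo.template,
                                              (chain, fx.ethylene_oxide()))
                    if m.side == "a"]
            (applied,) = apply_match(m)
            reactions.append(applied.reaction)
            chain = applied.products[0]
        lib = deduplicate(extract_template(r) for r in reactions)
        assert len(lib) == 1
        assert lib[0].occurrence_count == 3

    def test_order_independence(self, peo, da_template, sn2_template,
                                hydride_template):
        pool = [peo.template, da_template, sn2_template, hydride_template,
                extract_template(fx.shuffled_reaction(peo.reaction, 4)),
                extract_template(reverse(fx.sn2()))]
        rng = random.Random(0)
        reference = deduplicate(pool)
        for _ in range(5):
            shuffled = pool[:]
            rng.shuffle(shuffled)
            lib = deduplicate(shuffled)
            assert len(lib) == len(reference)
            for t in lib:
                assert any(templates_isomorphic(t, r, shape_strict=False)
                           for r in reference)


class TestGED:
    def test_identity_is_zero(self, sn2_template):
        assert template_ged(sn2_template, sn2_template) == 0.0

    def test_relabeled_pair_is_zero(self, peo):
        t2 = extract_template(fx.shuffled_reaction(peo.reaction, 5))
        assert template_ged(peo.template, t2) == 0.0

    def test_single_atom_relabel_costs_two(self):
        assert template_ged(tiny_transfer_template("C"),
                            tiny_transfer_template("N")) == 2.0

    def test_symmetry_and_nonnegativity(self, peo, hydride_template):
        d1 = template_ged(peo.template, hydride_template)
        d2 = template_ged(hydride_template, peo.template)
        assert d1 == d2 >= 0

    def test_triangle_inequality_spot_check(self):
        a = tiny_transfer_template("C")
        b = tiny_transfer_template("N")
        c = tiny_transfer_template("O")
        dab = template_ged(a, b)
        dbc = template_ged(b, c)
        dac = template_ged(a, c)
        assert dac <= dab + dbc

    def test_large_pair_warns_and_bounds(self, da_template, sn2_template):
        with pytest.warns(Warning):
            d = template_ged(da_template, sn2_template)
        assert d > 0


class TestGEDMatrix:
    def test_single_entry(self, peo):
        mat, order = ged_matrix(TemplateLibrary([peo.template]))
        assert mat.shape == (1, 1) and mat[0, 0] == 0 and order == [0]

    def test_identical_templates_zero_matrix(self, peo):
        t2 = extract_template(fx.shuffled_reaction(peo.reaction, 6))
        mat, _ = ged_matrix(TemplateLibrary([peo.template, t2]))
        assert (mat == 0).all()

    def test_symmetric_zero_diagonal_barrier_order(self, peo,
                                                   hydride_template):
        lib = TemplateLibrary([peo.template, hydride_template,
                               tiny_transfer_template("C")])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat, order = ged_matrix(lib)
        assert (mat == mat.T).all()
        assert (mat.diagonal() == 0).all()
        barriers = [lib[i].min_recorded_barrier() for i in order]
        assert barriers == sorted(barriers)  # 5.0 (hydride), 50.0, 72.0


class TestSpectrum:
    def test_single_template_network(self, peo):
        reactions = [peo.reaction,
                     fx.shuffled_reaction(peo.reaction, 1),
                     fx.shuffled_reaction(peo.reaction, 2)]
        lib = TemplateLibrary([peo.template])
        spectrum = barrier_spectrum(lib, reactions)
        assert len(spectrum.entries) == 1
        assert spectrum.entries[0].count == 3
        assert len(spectrum.new_templates) == 0

    def test_empty_network(self, peo):
        spectrum = barrier_spectrum(TemplateLibrary([peo.template]), [])
        assert spectrum.entries == [] and len(spectrum.new_templates) == 0

    def test_mixed_network_with_unknown_template(self, peo, sn2_template):
        import dataclasses
        elongations = [
            dataclasses.replace(fx.shuffled_reaction(peo.reaction, s),
                                barrier_fwd=b, barrier_bwd=b + 30.0)
            for s, b in ((1, 70.0), (2, 75.0), (3, 120.0))]
        lib = TemplateLibrary([peo.template, sn2_template])
        spectrum = barrier_spectrum(lib, elongations + [fx.hydride_abstraction()])
        assert len(spectrum.entries) == 1  # only the elongation occurs
        entry = spectrum.entries[0]
        assert entry.count == 3
        assert entry.min_barrier == 70.0
        assert sorted(entry.barriers) == [70.0, 75.0, 120.0]
        assert len(spectrum.new_templates) == 1  # the hydride abstraction


class TestLibrarySerialization:
    def test_round_trip_is_lossless(self, peo, da_template, sn2_template):
        lib = deduplicate([peo.template, da_template, sn2_template])
        back = TemplateLibrary.from_json(lib.to_json())
        assert len(back) == len(lib)
        for t1, t2 in zip(lib, back):
            assert templates_isomorphic(t1, t2)
            assert t1.barriers_ab == t2.barriers_ab
            assert t1.occurrence_count == t2.occurrence_count

    def test_unknown_schema_rejected(self):
        with pytest.raises(TemplateError):
            TemplateLibrary.from_json('{"schema": "something-else"}')
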