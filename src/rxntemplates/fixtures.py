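"""Programmatic worked examples and random-instance generators.

Everything needed to exercise the package without external data: the
Diels–Alder and SN2 textbook reactions, the anionic epoxide polymerization
systems (ethylene oxide and propylene oxide) with their chain-elongation
templates, a hydride-abstraction step, and seeded random reactions for
property tests.  Hydrogens are explicit throughout, and every generated
reaction passes :func:`rxntemplates.reactions.validate`.

The attached energies (kJ/mol) are fixture values chosen to be chemically
plausible, not computed: the main chain-elongation barrier is 72 kJ/mol
with a reaction energy of −30 kJ/mol (backward barrier 102 kJ/mol); the
hydride abstraction is nearly barrierless and strongly exothermic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .molgraph import MolecularGraph, build_graph
from .reactions import BondChange, MappedReaction
from .templates import (
    ReactionTemplate,
    TemplateAtom,
    TemplateSide,
    extract_template,
)

__all__ = [
    "ethylene_oxide", "ethoxide", "propylene_oxide", "propan_2_olate",
    "butadiene", "ethylene", "cyclopentadiene",
    "diels_alder", "sn2", "hydride_abstraction",
    "peo_system", "ppo_system", "cyclic_diene_system",
    "hand_built_elongation_template",
    "random_molecule", "random_reaction",
    "permute_graph", "shuffled_reaction",
    "scine_mini_export",
]

ELONGATION_BARRIER = 72.0        # kJ/mol, forward
ELONGATION_ENERGY = -30.0        # kJ/mol
HYDRIDE_BARRIER = 5.0            # kJ/mol
HYDRIDE_ENERGY = -200.0          # kJ/mol


# ---------------------------------------------------------------------------
# Molecules


def ethylene_oxide() -> MolecularGraph:
    """The three-membered epoxide ring, hydrogens explicit."""
    return build_graph(
        ["O", "C", "C", "H", "H", "H", "H"],
        [(0, 1), (0, 2), (1, 2), (1, 3), (1, 4), (2, 5), (2, 6)])


def ethoxide() -> MolecularGraph:
    """CH3CH2O^-  (also the ethanolate of the hydride-abstraction step)."""
    return build_graph(
        ["O", "C", "C", "H", "H", "H", "H", "H"],
        [(0, 1), (1, 2), (1, 3), (1, 4), (2, 5), (2, 6), (2, 7)],
        charge=-1, formal_charges=[-1, 0, 0, 0, 0, 0, 0, 0])


def propylene_oxide() -> MolecularGraph:
    """Methyl-substituted epoxide; atom 1 is CH2, atom 2 the CH center."""
    return build_graph(
        ["O", "C", "C", "C", "H", "H", "H", "H", "H", "H"],
        [(0, 1), (0, 2), (1, 2), (2, 3),
         (1, 4), (1, 5), (2, 6), (3, 7), (3, 8), (3, 9)])


def propan_2_olate() -> MolecularGraph:
    """(CH3)2CH-O^-, an achiral alkoxide initiator."""
    return build_graph(
        ["O", "C", "C", "C", "H", "H", "H", "H", "H", "H", "H"],
        [(0, 1), (1, 2), (1, 3), (1, 4),
         (2, 5), (2, 6), (2, 7), (3, 8), (3, 9), (3, 10)],
        charge=-1, formal_charges=[-1] + [0] * 10)


def butadiene() -> MolecularGraph:
    """s-cis 1,3-butadiene as a binary-bond graph (C0-C1-C2-C3 chain)."""
    return build_graph(
        ["C", "C", "C", "C", "H", "H", "H", "H", "H", "H"],
        [(0, 1), (1, 2), (2, 3),
         (0, 4), (0, 5), (1, 6), (2, 7), (3, 8), (3, 9)])


def ethylene() -> MolecularGraph:
    return build_graph(["C", "C", "H", "H", "H", "H"],
                       [(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)])


def cyclopentadiene() -> MolecularGraph:
    """Cyclic diene; the diene termini C0 and C3 are three-coordinate."""
    return build_graph(
        ["C", "C", "C", "C", "C", "H", "H", "H", "H", "H", "H"],
        [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0),
         (0, 5), (1, 6), (2, 7), (3, 8), (4, 9), (4, 10)])


def chloride() -> MolecularGraph:
    return build_graph(["Cl"], [], charge=-1)


def methyl_bromide() -> MolecularGraph:
    return build_graph(["C", "Br", "H", "H", "H"],
                       [(0, 1), (0, 2), (0, 3), (0, 4)])


# ---------------------------------------------------------------------------
# Worked-example reactions


def diels_alder() -> MappedReaction:
    """Butadiene + ethylene -> cyclohexene (binary bonds: 2 formed, 0 broken).

    The product reuses the reactant-side global atom order, so the atom map
    is the identity.
    """
    lhs = (butadiene(), ethylene())
    lhs_bonds = [(0, 1), (1, 2), (2, 3), (0, 4), (0, 5), (1, 6), (2, 7),
                 (3, 8), (3, 9),
                 (10, 11), (10, 12), (10, 13), (11, 14), (11, 15)]
    cyclohexene = build_graph(
        ["C", "C", "C", "C", "H", "H", "H", "H", "H", "H",
         "C", "C", "H", "H", "H", "H"],
        lhs_bonds + [(3, 10), (0, 11)])
    return MappedReaction(lhs=lhs, rhs=(cyclohexene,),
                          atom_map=tuple(range(16)),
                          barrier_fwd=110.0, barrier_bwd=180.0,
                          reaction_energy=-70.0)


def sn2() -> MappedReaction:
    """Cl^- + CH3Br -> CH3Cl + Br^-  (1 bond formed, 1 broken)."""
    lhs = (chloride(), methyl_bromide())
    ch3cl = build_graph(["Cl", "C", "H", "H", "H"],
                        [(0, 1), (1, 2), (1, 3), (1, 4)])
    bromide = build_graph(["Br"], [], charge=-1)
    # lhs global: Cl=0, C=1, Br=2, H=3,4,5
    return MappedReaction(lhs=lhs, rhs=(ch3cl, bromide),
                          atom_map=(0, 1, 5, 2, 3, 4),
                          barrier_fwd=60.0, barrier_bwd=75.0,
                          reaction_energy=-15.0)


def peo_elongation() -> MappedReaction:
    """Ethoxide + ethylene oxide -> ring-opened n=1 alkoxide."""
    lhs = (ethoxide(), ethylene_oxide())
    # global: ethoxide 0-7; epoxide O=8, C=9, C=10, H=11..14
    n1 = build_graph(
        ["O", "C", "C", "H", "H", "H", "H", "H",
         "O", "C", "C", "H", "H", "H", "H"],
        [(0, 1), (1, 2), (1, 3), (1, 4), (2, 5), (2, 6), (2, 7),
         (0, 9), (8, 10), (9, 10), (9, 11), (9, 12), (10, 13), (10, 14)],
        charge=-1, formal_charges=[0] * 8 + [-1] + [0] * 6)
    return MappedReaction(lhs=lhs, rhs=(n1,), atom_map=tuple(range(15)),
                          barrier_fwd=ELONGATION_BARRIER,
                          barrier_bwd=ELONGATION_BARRIER - ELONGATION_ENERGY,
                          reaction_energy=ELONGATION_ENERGY)


def ppo_elongation() -> MappedReaction:
    """Propan-2-olate + propylene oxide, attack at the unsubstituted carbon."""
    lhs = (propan_2_olate(), propylene_oxide())
    # global: initiator 0-10; epoxide O=11, CH2=12, CH=13, CH3=14, H=15..20
    product = build_graph(
        ["O", "C", "C", "C", "H", "H", "H", "H", "H", "H", "H",
         "O", "C", "C", "C", "H", "H", "H", "H", "H", "H"],
        [(0, 1), (1, 2), (1, 3), (1, 4), (2, 5), (2, 6), (2, 7),
         (3, 8), (3, 9), (3, 10),
         (0, 12), (11, 13), (12, 13), (13, 14),
         (12, 15), (12, 16), (13, 17), (14, 18), (14, 19), (14, 20)],
        charge=-1, formal_charges=[0] * 11 + [-1] + [0] * 9)
    return MappedReaction(lhs=lhs, rhs=(product,), atom_map=tuple(range(21)),
                          barrier_fwd=ELONGATION_BARRIER,
                          barrier_bwd=ELONGATION_BARRIER - ELONGATION_ENERGY,
                          reaction_energy=ELONGATION_ENERGY)


def hydride_abstraction() -> MappedReaction:
    """Ethoxide -> acetaldehyde + hydride (binary bonds: 1 broken)."""
    lhs = (ethoxide(),)
    acetaldehyde = build_graph(
        ["O", "C", "C", "H", "H", "H", "H"],
        [(0, 1), (1, 2), (1, 3), (2, 4), (2, 5), (2, 6)])
    hydride = build_graph(["H"], [], charge=-1)
    return MappedReaction(lhs=lhs, rhs=(acetaldehyde, hydride),
                          atom_map=(0, 1, 2, 7, 3, 4, 5, 6),
                          barrier_fwd=HYDRIDE_BARRIER,
                          barrier_bwd=HYDRIDE_BARRIER - HYDRIDE_ENERGY,
                          reaction_energy=HYDRIDE_ENERGY)


# ---------------------------------------------------------------------------
# Polymerization systems


def hand_built_elongation_template() -> ReactionTemplate:
    """The chain-elongation template written down by hand.

    Side a: a terminal alkoxide O^- (own molecule) plus a C-O fragment of
    the epoxide ring; side b: the new ether C-O bond plus the liberated
    terminal O^-.  Isomorphic to the template extracted from the
    elongation reaction.
    """
    side_a = TemplateSide(
        atoms=(TemplateAtom("O", frozenset({"terminal"})),
               TemplateAtom("C", frozenset({"tetrahedron"})),
               TemplateAtom("O", frozenset({"bent"}))),
        bonds=frozenset({(1, 2)}),
        fragment_of=(0, 1, 1),
        molecule_of_fragment=(0, 1),
        formal_charges=(-1, 0, 0),
    )
    side_b = TemplateSide(
        atoms=(TemplateAtom("O", frozenset({"bent"})),
               TemplateAtom("C", frozenset({"tetrahedron"})),
               TemplateAtom("O", frozenset({"terminal"}))),
        bonds=frozenset({(0, 1)}),
        fragment_of=(0, 0, 1),
        molecule_of_fragment=(0, 0),
        formal_charges=(0, 0, -1),
    )
    return ReactionTemplate(
        side_a=side_a, side_b=side_b, cross_map=(0, 1, 2),
        barriers_ab=(ELONGATION_BARRIER,),
        barriers_ba=(ELONGATION_BARRIER - ELONGATION_ENERGY,),
        label="chain_elongation",
    )


@dataclass
class PolymerizationSystem:
    """Start compounds, the seed reaction, its template and a table oracle."""

    start: tuple[MolecularGraph, ...]
    monomer: MolecularGraph
    reaction: MappedReaction
    template: ReactionTemplate
    oracle_table: dict


def peo_system() -> PolymerizationSystem:
    """Anionic ethylene-oxide polymerization from ethoxide."""
    r = peo_elongation()
    return PolymerizationSystem(
        start=(ethoxide(), ethylene_oxide()),
        monomer=ethylene_oxide(),
        reaction=r,
        template=extract_template(r, label="chain_elongation"),
        oracle_table={"chain_elongation": (ELONGATION_BARRIER,
                                           ELONGATION_ENERGY)},
    )


def ppo_system() -> PolymerizationSystem:
    """Anionic propylene-oxide polymerization from propan-2-olate."""
    r = ppo_elongation()
    return PolymerizationSystem(
        start=(propan_2_olate(), propylene_oxide()),
        monomer=propylene_oxide(),
        reaction=r,
        template=extract_template(r, label="chain_elongation"),
        oracle_table={"chain_elongation": (ELONGATION_BARRIER,
                                           ELONGATION_ENERGY)},
    )


def cyclic_diene_system() -> tuple[ReactionTemplate, tuple[MolecularGraph, ...]]:
    """The Diels–Alder template plus a cyclic-diene reactant pair.

    Because the template keeps only the reactive atoms (no spanning trees),
    it must still match when the diene is cyclic.
    """
    t = extract_template(diels_alder(), label="diels_alder")
    return t, (cyclopentadiene(), ethylene())


# ---------------------------------------------------------------------------
# Relabeling helpers


def permute_graph(g: MolecularGraph, perm: list[int]) -> MolecularGraph:
    """Relabel atoms: ``perm[old] = new`` position.  Shapes reassigned."""
    n = g.n_atoms
    inv = [0] * n
    for old, new in enumerate(perm):
        inv[new] = old
    from .molgraph import assign_shapes

    return assign_shapes(MolecularGraph(
        elements=tuple(g.elements[inv[p]] for p in range(n)),
        bonds=frozenset(tuple(sorted((perm[a], perm[b]))) for a, b in g.bonds),
        charge=g.charge,
        shapes=("isolated",) * n,
        stereo=tuple(g.stereo[inv[p]] for p in range(n)),
        formal_charges=tuple(g.formal_charges[inv[p]] for p in range(n)),
    ))


def shuffled_reaction(r: MappedReaction, seed: int) -> MappedReaction:
    """The same reaction with atoms randomly relabeled within each molecule.

    The atom map is adjusted accordingly, so the result stays valid and
    describes an identical chemical change.
    """
    rng = random.Random(seed)

    def permute_side(side):
        perms, new_side, global_perm, off = [], [], [], 0
        for g in side:
            p = list(range(g.n_atoms))
            rng.shuffle(p)
            new_side.append(permute_graph(g, p))
            global_perm.extend(off + p[a] for a in range(g.n_atoms))
            off += g.n_atoms
        return tuple(new_side), global_perm

    lhs, pl = permute_side(r.lhs)
    rhs, pr = permute_side(r.rhs)
    new_map = [0] * len(r.atom_map)
    for i, j in enumerate(r.atom_map):
        new_map[pl[i]] = pr[j]
    return MappedReaction(lhs=lhs, rhs=rhs, atom_map=tuple(new_map),
                          barrier_fwd=r.barrier_fwd,
                          barrier_bwd=r.barrier_bwd,
                          reaction_energy=r.reaction_energy)


# ---------------------------------------------------------------------------
# Random instances for property tests


def random_molecule(rng: random.Random, n_atoms: int = 6,
                    extra_edges: int = 1,
                    elements: tuple[str, ...] = ("C", "N", "O", "H"),
                    ) -> MolecularGraph:
    """A random connected molecular graph (spanning tree + extra edges)."""
    els = [rng.choice(elements) for _ in range(n_atoms)]
    bonds = {(rng.randrange(i), i) for i in range(1, n_atoms)}
    candidates = [(a, b) for a in range(n_atoms) for b in range(a + 1, n_atoms)
                  if (a, b) not in bonds]
    rng.shuffle(candidates)
    bonds.update(candidates[:extra_edges])
    return build_graph(els, sorted(bonds))


def random_reaction(seed: int, n_atoms: int = 8, extra_edges: int = 2
                    ) -> tuple[MappedReaction, BondChange]:
    """A random reaction built by planting a random edit into a random graph.

    Returns the reaction together with the planted bond change; the product
    atom order is a random permutation of the reactant order, and the
    products are the connected components of the edited graph.  Always
    passes validation; detection must recover exactly the planted edit.
    """
    rng = random.Random(seed)
    g = random_molecule(rng, n_atoms=n_atoms, extra_edges=extra_edges)
    bonds = set(g.bonds)
    non_edges = [(a, b) for a in range(n_atoms) for b in range(a + 1, n_atoms)
                 if (a, b) not in bonds]
    while True:
        k_break = rng.randint(0, min(2, len(bonds)))
        k_form = rng.randint(0, min(2, len(non_edges)))
        if k_break + k_form > 0:
            break
    broken = set(rng.sample(sorted(bonds), k_break))
    formed = set(rng.sample(non_edges, k_form))
    new_bonds = (bonds - broken) | formed

    perm = list(range(n_atoms))          # product position -> reactant atom
    rng.shuffle(perm)
    inv = {orig: pos for pos, orig in enumerate(perm)}
    permuted = MolecularGraph(
        elements=tuple(g.elements[perm[p]] for p in range(n_atoms)),
        bonds=frozenset(tuple(sorted((inv[a], inv[b]))) for a, b in new_bonds),
        charge=0,
        shapes=("isolated",) * n_atoms,
        stereo=(None,) * n_atoms,
        formal_charges=(0,) * n_atoms,
    )
    from .molgraph import split_components

    comps, atom_lists = split_components(permuted)
    rhs_global = {}
    pos = 0
    for comp_atoms in atom_lists:
        for a in comp_atoms:
            rhs_global[a] = pos
            pos += 1
    reaction = MappedReaction(
        lhs=(g,), rhs=tuple(comps),
        atom_map=tuple(rhs_global[inv[i]] for i in range(n_atoms)))
    return reaction, BondChange(frozenset(formed), frozenset(broken))


# ---------------------------------------------------------------------------
# Synthetic SCINE-style export


def _structure_record(g: MolecularGraph) -> dict:
    return {"elements": list(g.elements),
            "bonds": sorted([a, b, 1.0] for a, b in g.bonds),
            "charge": g.charge,
            "formal_charges": list(g.formal_charges)}


def scine_mini_export() -> dict:
    """A tiny synthetic network export in the adapter's snapshot schema.

    Three valid elementary steps (two chain elongations, one hydride
    abstraction) plus one defective record without an atom map, with
    energies stored in Hartree as a database would hold them.  This is a
    constructed stand-in for a deposited network dump, shaped like one but
    invented here.
    """
    h = 2625.499639  # kJ/mol per Hartree
    peo = peo_elongation()
    n1 = peo.rhs[0]
    # second elongation: n1 + ethylene oxide -> n2 (identity atom order)
    eo = ethylene_oxide()
    # O8 of the chain attacks C16 of the fresh epoxide; ring bond 15-16 breaks
    n2 = build_graph(
        list(n1.elements) + list(eo.elements),
        sorted([a, b] for a, b in n1.bonds)
        + [[8, 16], [15, 17], [16, 17],
           [16, 18], [16, 19], [17, 20], [17, 21]],
        charge=-1, formal_charges=[0] * 15 + [-1] + [0] * 6)
    hyd = hydride_abstraction()

    structures = {
        "s-ethoxide": _structure_record(ethoxide()),
        "s-eo": _structure_record(eo),
        "s-n1": _structure_record(n1),
        "s-n2": _structure_record(n2),
        "s-acetaldehyde": _structure_record(hyd.rhs[0]),
        "s-hydride": _structure_record(hyd.rhs[1]),
    }
    steps = {
        "es-1": {"reactants": ["s-ethoxide", "s-eo"], "products": ["s-n1"],
                 "atom_map": [[i, i] for i in range(15)],
                 "energies": {"reactant": 0.0,
                              "ts": ELONGATION_BARRIER / h,
                              "product": ELONGATION_ENERGY / h}},
        "es-2": {"reactants": ["s-n1", "s-eo"], "products": ["s-n2"],
                 "atom_map": [[i, i] for i in range(22)],
                 "energies": {"reactant": 0.0,
                              "ts": (ELONGATION_BARRIER + 8.0) / h,
                              "product": ELONGATION_ENERGY / h}},
        "es-3": {"reactants": ["s-ethoxide"],
                 "products": ["s-acetaldehyde", "s-hydride"],
                 "atom_map": [[0, 0], [1, 1], [2, 2], [3, 7],
                              [4, 3], [5, 4], [6, 5], [7, 6]],
                 "energies": {"reactant": 0.0,
                              "ts": HYDRIDE_BARRIER / h,
                              "product": HYDRIDE_ENERGY / h}},
        "es-broken": {"reactants": ["s-ethoxide", "s-eo"],
                      "products": ["s-n1"],
                      "energies": {"reactant": 0.0, "ts": 0.02,
                                   "product": -0.01}},
    }
    compounds = {f"c-{k[2:]}": {"structures": [k]} for k in structures}
    reactions = {
        "r-1": {"steps": ["es-1"], "lhs_compounds": ["c-ethoxide", "c-eo"],
                "rhs_compounds": ["c-n1"]},
        "r-2": {"steps": ["es-2"], "lhs_compounds": ["c-n1", "c-eo"],
                "rhs_compounds": ["c-n2"]},
        "r-3": {"steps": ["es-3", "es-broken"],
                "lhs_compounds": ["c-ethoxide"],
                "rhs_compounds": ["c-acetaldehyde", "c-hydride"]},
    }
    return {"format": "scine-db-export/1.1.0",
            "structures": structures, "compounds": compounds,
            "elementary_steps": steps, "reactions": reactions}
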