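"""Template application: match templates to reactants, generate products.

A template matches a set of reactant graphs when all fragments of one of
its sides can be embedded without overlapping atoms, with every fragment of
one template molecule landing in a single reactant molecule and distinct
template molecules in distinct reactants.  All distinct ways of matching
are reported; matches that coincide up to symmetry (automorphisms of the
template side or of the reactant graphs) are collapsed, because they would
generate the same reaction trial.

Applying a match edits the reactant union graph with the template's bond
changes (translated through the match), transfers the template's
product-side formal charges to the matched atoms, assigns stereo
descriptors at any newly created four-distinct-branch center (one product
variant per descriptor value) and splits the result into product
molecules, together with the induced atom-mapped reaction record.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .canonical import canonical_certificate
from .molgraph import (
    MolecularGraph,
    assign_shapes,
    split_components,
    subgraph_embeddings,
)
from .reactions import MappedReaction
from .templates import ReactionTemplate, TemplateLibrary, TemplateSide

__all__ = [
    "TemplateMatch",
    "AppliedReaction",
    "Trial",
    "MatchApplicationError",
    "match_template",
    "apply_match",
    "allowed",
    "enumerate_trials",
]

HostAtom = tuple[int, int]  # (reactant index, atom index)


class MatchApplicationError(ValueError):
    """Raised when applying a match would create an invalid graph edit."""


@dataclass(frozen=True)
class TemplateMatch:
    """One way of placing a template side onto a set of reactants."""

    template: ReactionTemplate
    side: str  # "a" or "b": which template side was matched
    reactants: tuple[MolecularGraph, ...]
    molecule_assignment: tuple[int, ...]  # template molecule -> reactant
    assignment: tuple[HostAtom, ...]      # template side atom -> host atom
    certificate: str = ""

    @property
    def matched_side(self) -> TemplateSide:
        return (self.template.side_a if self.side == "a"
                else self.template.side_b)

    @property
    def direction(self) -> str:
        """Reaction direction implied by the matched side."""
        return "ab" if self.side == "a" else "ba"

    def host_edits(self) -> tuple[frozenset, frozenset]:
        """Expected bond changes on the reactants: (formed, broken) pairs
        of host atoms."""
        t = self.template
        if self.side == "a":
            add, remove = t.formed, t.broken
            local = lambda pair: pair
        else:
            cm = t.cross_map
            add = {tuple(sorted((cm[a], cm[b]))) for a, b in t.broken}
            remove = {tuple(sorted((cm[a], cm[b]))) for a, b in t.formed}
            local = lambda pair: pair
        amap = self.assignment
        formed = frozenset(tuple(sorted((amap[a], amap[b])))
                           for a, b in map(local, add))
        broken = frozenset(tuple(sorted((amap[a], amap[b])))
                           for a, b in map(local, remove))
        return formed, broken


@dataclass(frozen=True)
class AppliedReaction:
    """Products of a template application plus the induced reaction record."""

    products: tuple[MolecularGraph, ...]
    reaction: MappedReaction


@dataclass(frozen=True)
class Trial:
    """A reaction trial the template filter lets through: a match and the
    bond rearrangement it intends."""

    match: TemplateMatch
    formed: frozenset
    broken: frozenset


# ---------------------------------------------------------------------------
# Matching


def _match_certificate(side: TemplateSide, side_tag: str,
                       reactants: Sequence[MolecularGraph],
                       assignment: dict[int, HostAtom]) -> str:
    """Canonical certificate of the reactants-plus-role-assignment graph.

    Two matches with equal certificates are related by symmetry (template
    and/or host automorphisms) and would produce isomorphic trials.
    """
    nodes: list = []
    labels: list = []
    index: dict = {}

    def add(node, label):
        index[node] = len(nodes)
        nodes.append(node)
        labels.append(label)

    matched_hosts = set(assignment.values())
    # host atoms, with plain terminal hydrogens folded
    folded: dict[HostAtom, int] = {}
    for ri, g in enumerate(reactants):
        adj = g.adjacency()
        for i in range(g.n_atoms):
            h = (ri, i)
            if (g.elements[i] == "H" and g.stereo[i] is None
                    and len(adj[i]) == 1 and g.elements[adj[i][0]] != "H"
                    and h not in matched_hosts):
                heavy = (ri, adj[i][0])
                folded[heavy] = folded.get(heavy, 0) + 1
    for ri, g in enumerate(reactants):
        for i in range(g.n_atoms):
            h = (ri, i)
            adjn = g.neighbors(i)
            if (g.elements[i] == "H" and g.stereo[i] is None
                    and len(adjn) == 1 and g.elements[adjn[0]] != "H"
                    and h not in matched_hosts):
                continue
            add(("h", ri, i),
                ("host", g.elements[i], g.stereo[i], folded.get(h, 0)))
        add(("hm", ri), ("hostmol", g.charge))
    for i, atom in enumerate(side.atoms):
        add(("t", i), ("tatom", side_tag, atom.element,
                       tuple(sorted(atom.allowed_shapes))))
    for f in range(side.n_fragments):
        add(("tf", f), ("tfrag", side_tag))
    for m in range(side.n_molecules):
        add(("tm", m), ("tmol", side_tag))

    adjlists: list[list[int]] = [[] for _ in nodes]

    def link(u, v):
        iu, iv = index[u], index[v]
        adjlists[iu].append(iv)
        adjlists[iv].append(iu)

    for ri, g in enumerate(reactants):
        for a, b in g.bonds:
            if ("h", ri, a) in index and ("h", ri, b) in index:
                link(("h", ri, a), ("h", ri, b))
        for i in range(g.n_atoms):
            if ("h", ri, i) in index:
                link(("h", ri, i), ("hm", ri))
    for a, b in side.bonds:
        link(("t", a), ("t", b))
    for i, f in enumerate(side.fragment_of):
        link(("t", i), ("tf", f))
    for f, m in enumerate(side.molecule_of_fragment):
        link(("tf", f), ("tm", m))
    for ti, (ri, ai) in assignment.items():
        link(("t", ti), ("h", ri, ai))
    return canonical_certificate(adjlists, labels)


def _disjoint_fragment_placements(
    side: TemplateSide, frags: Sequence[int], host: MolecularGraph
) -> list[dict[int, int]]:
    """All ways to embed the given fragments atom-disjointly into one host.

    Returns maps from template side atom index to host atom index.
    """
    per_frag = []
    for f in frags:
        pattern, atom_ids = side.fragment_pattern(f)
        embs = subgraph_embeddings(pattern, host)
        if not embs:
            return []
        per_frag.append((atom_ids, embs))
    placements: list[dict[int, int]] = []

    def backtrack(k: int, used: set[int], acc: dict[int, int]):
        if k == len(per_frag):
            placements.append(dict(acc))
            return
        atom_ids, embs = per_frag[k]
        for emb in embs:
            hosts = emb.host_atoms
            if hosts & used:
                continue
            m = emb.as_dict
            for local, tidx in enumerate(atom_ids):
                acc[tidx] = m[local]
            backtrack(k + 1, used | hosts, acc)
            for tidx in atom_ids:
                del acc[tidx]

    backtrack(0, set(), {})
    return placements


def match_template(t: ReactionTemplate,
                   reactants: Sequence[MolecularGraph]) -> list[TemplateMatch]:
    """All symmetry-distinct placements of either template side.

    Fragments of one template molecule are constrained to a single reactant
    molecule, distinct template molecules to distinct reactants, and a side
    only applies when its molecule count equals the reactant count.
    Deterministically ordered; an empty list means no match.
    """
    reactants = tuple(reactants)
    out: list[TemplateMatch] = []
    for tag, side in (("a", t.side_a), ("b", t.side_b)):
        if side.n_molecules != len(reactants):
            continue
        mols = range(side.n_molecules)
        seen: set[str] = set()
        for perm in itertools.permutations(range(len(reactants))):
            per_mol: list[list[dict[int, int]]] = []
            ok = True
            for m in mols:
                host = reactants[perm[m]]
                placements = _disjoint_fragment_placements(
                    side, side.molecule_fragments(m), host)
                if not placements:
                    ok = False
                    break
                per_mol.append(placements)
            if not ok:
                continue
            for combo in itertools.product(*per_mol):
                assignment: dict[int, HostAtom] = {}
                for m, placement in enumerate(combo):
                    for tidx, hidx in placement.items():
                        assignment[tidx] = (perm[m], hidx)
                cert = _match_certificate(side, tag, reactants, assignment)
                if cert in seen:
                    continue
                seen.add(cert)
                out.append(TemplateMatch(
                    template=t, side=tag, reactants=reactants,
                    molecule_assignment=tuple(perm[m] for m in mols),
                    assignment=tuple(assignment[i]
                                     for i in range(side.n_atoms)),
                    certificate=cert,
                ))
    out.sort(key=lambda m: (m.side, m.molecule_assignment, m.assignment))
    return out


# ---------------------------------------------------------------------------
# Application


def _branch_certificates(elements, bonds_adj, stereo, center: int
                         ) -> Optional[list[str]]:
    """Certificates of the four branches around *center*, or None if the
    center does not have exactly four neighbors."""
    nbrs = bonds_adj[center]
    if len(nbrs) != 4:
        return None
    certs = []
    for root in nbrs:
        # component containing root in the graph with center removed
        seen = {root}
        stack = [root]
        while stack:
            for u in bonds_adj[stack.pop()]:
                if u != center and u not in seen:
                    seen.add(u)
                    stack.append(u)
        order = sorted(seen)
        local = {v: i for i, v in enumerate(order)}
        adj: list[list[int]] = [[] for _ in order]
        for v in order:
            for u in bonds_adj[v]:
                if u in local and local[u] > local[v]:
                    adj[local[v]].append(local[u])
                    adj[local[u]].append(local[v])
        labels = [(elements[v], stereo[v], v == root) for v in order]
        certs.append(canonical_certificate(adj, labels))
    return certs


def apply_match(m: TemplateMatch) -> list[AppliedReaction]:
    """Generate product graphs by applying the matched bond changes.

    Returns one :class:`AppliedReaction` per stereo variant (several only
    when the edit creates new stereocenters).  Element multiset and total
    charge are conserved; the returned reaction carries the
    identity-outside-the-template atom map.

    Raises :class:`MatchApplicationError` if the edit would duplicate an
    existing bond.
    """
    t = m.template
    reactants = m.reactants
    offsets = []
    total = 0
    for g in reactants:
        offsets.append(total)
        total += g.n_atoms

    def uidx(h: HostAtom) -> int:
        return offsets[h[0]] + h[1]

    elements: list[str] = []
    stereo: list = []
    fcs: list[int] = []
    bonds: set = set()
    for off, g in zip(offsets, reactants):
        elements.extend(g.elements)
        stereo.extend(g.stereo)
        fcs.extend(g.formal_charges)
        for a, b in g.bonds:
            bonds.add((a + off, b + off))

    formed_h, broken_h = m.host_edits()
    to_add = {tuple(sorted((uidx(a), uidx(b)))) for a, b in formed_h}
    to_remove = {tuple(sorted((uidx(a), uidx(b)))) for a, b in broken_h}
    for e in to_add:
        if e in bonds:
            raise MatchApplicationError(
                f"edit would duplicate existing bond {e}")
    for e in to_remove:
        if e not in bonds:
            raise MatchApplicationError(f"edit removes a missing bond {e}")
    new_bonds = (bonds - to_remove) | to_add

    # transfer the template's opposite-side formal charges to matched atoms
    if m.side == "a":
        other, idx_of = t.side_b, lambda i: t.cross_map[i]
    else:
        inv = {j: i for i, j in enumerate(t.cross_map)}
        other, idx_of = t.side_a, lambda i: inv[i]
    for ti, h in enumerate(m.assignment):
        fcs[uidx(h)] = other.formal_charges[idx_of(ti)]

    adj: list[list[int]] = [[] for _ in elements]
    for a, b in new_bonds:
        adj[a].append(b)
        adj[b].append(a)

    edited = sorted({v for e in (to_add | to_remove) for v in e})
    new_centers: list[int] = []
    base_stereo = list(stereo)
    for v in edited:
        certs = _branch_certificates(elements, adj, stereo, v)
        if certs is not None and len(set(certs)) == 4:
            new_centers.append(v)
        else:
            base_stereo[v] = None

    variant_stereos: list[list] = []
    if new_centers:
        for combo in itertools.product("AB", repeat=len(new_centers)):
            s = list(base_stereo)
            for v, d in zip(new_centers, combo):
                s[v] = d
            variant_stereos.append(s)
    else:
        variant_stereos.append(base_stereo)

    out: list[AppliedReaction] = []
    for var_stereo in variant_stereos:
        union = MolecularGraph(
            elements=tuple(elements), bonds=frozenset(new_bonds),
            charge=sum(fcs), shapes=("isolated",) * len(elements),
            stereo=tuple(var_stereo), formal_charges=tuple(fcs))
        comps, atom_lists = split_components(union)
        # product-side global index of each union atom
        rhs_index: dict[int, int] = {}
        pos = 0
        for comp_atoms in atom_lists:
            for a in comp_atoms:
                rhs_index[a] = pos
                pos += 1
        reaction = MappedReaction(
            lhs=reactants,
            rhs=tuple(comps),
            atom_map=tuple(rhs_index[i] for i in range(total)),
        )
        out.append(AppliedReaction(products=tuple(comps), reaction=reaction))
    return out


# ---------------------------------------------------------------------------
# Filtering


def allowed(t: ReactionTemplate, direction: str,
            threshold_kjmol: float) -> bool:
    """Template-application filter: the direction's lowest recorded barrier
    must exist and lie strictly below the threshold (unknown never passes).
    """
    b = t.min_barrier(direction)
    return b is not None and b < threshold_kjmol


def enumerate_trials(library: TemplateLibrary,
                     reactants: Sequence[MolecularGraph],
                     threshold_kjmol: float) -> list[Trial]:
    """All reaction trials the template filter admits for these reactants.

    Concatenates, over library entries whose matched direction passes
    :func:`allowed`, every symmetry-distinct match together with the bond
    changes it intends — the filter surface a network explorer consumes.
    """
    trials: list[Trial] = []
    for t in library:
        ok_dirs = {d for d in ("ab", "ba") if allowed(t, d, threshold_kjmol)}
        if not ok_dirs:
            continue
        for match in match_template(t, reactants):
            if match.direction not in ok_dirs:
                continue
            formed, broken = match.host_edits()
            trials.append(Trial(match=match, formed=formed, broken=broken))
    return trials
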