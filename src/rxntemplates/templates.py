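"""Reaction templates: extraction, deduplication, merging and GED analysis.

A reaction template abstracts a reaction down to the atoms whose bonding
pattern changes.  Retained per side are: those atoms (element plus a list
of allowed local shapes), their grouping into connected *fragments* and
into the *molecules* the fragments came from, the bonds among them, and the
cross-side atom mapping.  Everything else — spectator atoms, bond orders,
3D structure — is discarded.  Templates accumulate recorded barriers and an
occurrence count when duplicates are merged, which later drives the
template-application filter of the explorer.

Template identity is decided on a combined *template graph* containing
atom, fragment and molecule nodes (containment edges), the cross-side
mapping (a perfect matching between the sides' atom nodes) and the bond
edges, where a bond missing on the opposite side is labeled "changed".
Two templates are the same when these graphs are isomorphic under all
labels, allowing the two side roles to swap (a template equals its own
reverse reading).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .molgraph import Fragment, MolecularGraph
from .reactions import (
    BondChange,
    DegenerateReactionError,
    MappedReaction,
    detect_bond_changes,
    molecule_of_atom,
    side_offsets,
    side_union_bonds,
    validate,
)

__all__ = [
    "TemplateAtom",
    "TemplateSide",
    "ReactionTemplate",
    "TemplateLibrary",
    "TemplateError",
    "ApproximateGEDWarning",
    "extract_template",
    "build_template_graph",
    "templates_isomorphic",
    "find_isomorphism",
    "reverse_template",
    "merge",
    "deduplicate",
    "template_ged",
    "ged_matrix",
    "barrier_spectrum",
    "Spectrum",
    "SpectrumEntry",
    "template_to_dot",
    "GED_EXACT_MAX_TOTAL_NODES",
]

Pair = tuple[int, int]

#: Largest *combined* node count of the two template graphs for which the
#: edit distance is computed by exact search; beyond this an upper bound is
#: returned (flagged by :class:`ApproximateGEDWarning`).
GED_EXACT_MAX_TOTAL_NODES = 24


class TemplateError(ValueError):
    """Raised for invalid template operations (e.g. merging non-duplicates)."""


class ApproximateGEDWarning(UserWarning):
    """Emitted when a graph edit distance is an upper bound, not exact."""


@dataclass(frozen=True)
class TemplateAtom:
    """A template atom: element plus the set of local shapes it may adopt."""

    element: str
    allowed_shapes: frozenset[str]

    def __post_init__(self):
        if not self.allowed_shapes:
            raise TemplateError("template atom needs a non-empty shape list")


@dataclass(frozen=True)
class TemplateSide:
    """One side of a template: atoms with fragment/molecule grouping.

    ``fragment_of[i]`` is the fragment index of atom ``i``;
    ``molecule_of_fragment[f]`` the molecule index of fragment ``f``.
    Bonds are intra-fragment by construction (fragments are connected
    components of the reactive-atom-induced subgraph).
    """

    atoms: tuple[TemplateAtom, ...]
    bonds: frozenset[Pair]
    fragment_of: tuple[int, ...]
    molecule_of_fragment: tuple[int, ...]
    formal_charges: tuple[int, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_fragments(self) -> int:
        return len(self.molecule_of_fragment)

    @property
    def n_molecules(self) -> int:
        return len(set(self.molecule_of_fragment))

    def fragment_atoms(self, f: int) -> list[int]:
        return [i for i, g in enumerate(self.fragment_of) if g == f]

    def molecule_fragments(self, m: int) -> list[int]:
        return [f for f, mm in enumerate(self.molecule_of_fragment) if mm == m]

    def fragment_pattern(self, f: int) -> tuple[Fragment, list[int]]:
        """The fragment as a matching pattern plus its side-atom indices."""
        atoms = self.fragment_atoms(f)
        local = {a: k for k, a in enumerate(atoms)}
        return Fragment(
            elements=tuple(self.atoms[a].element for a in atoms),
            allowed_shapes=tuple(self.atoms[a].allowed_shapes for a in atoms),
            bonds=frozenset(tuple(sorted((local[a], local[b])))
                            for a, b in self.bonds
                            if a in local and b in local),
        ), atoms


@dataclass(frozen=True)
class ReactionTemplate:
    """A two-sided reaction template.

    ``cross_map[i]`` is the side-b atom index mapped to side-a atom ``i``.
    ``barriers_ab``/``barriers_ba`` are all recorded activation energies
    (kJ/mol) for the a->b and b->a directions; ``occurrence_count`` tallies
    how many source reactions were merged into this template.
    """

    side_a: TemplateSide
    side_b: TemplateSide
    cross_map: tuple[int, ...]
    barriers_ab: tuple[float, ...] = ()
    barriers_ba: tuple[float, ...] = ()
    occurrence_count: int = 1
    label: Optional[str] = None

    @property
    def broken(self) -> frozenset[Pair]:
        """Side-a bonds absent between the mapped side-b atoms."""
        return frozenset(
            (a, b) for a, b in self.side_a.bonds
            if tuple(sorted((self.cross_map[a], self.cross_map[b])))
            not in self.side_b.bonds)

    @property
    def formed(self) -> frozenset[Pair]:
        """Side-a atom pairs non-bonded on a but bonded between images on b."""
        inv = {j: i for i, j in enumerate(self.cross_map)}
        return frozenset(
            tuple(sorted((inv[a], inv[b]))) for a, b in self.side_b.bonds
            if tuple(sorted((inv[a], inv[b]))) not in self.side_a.bonds)

    def min_barrier(self, direction: str) -> Optional[float]:
        lst = self.barriers_ab if direction == "ab" else self.barriers_ba
        return min(lst) if lst else None

    def min_recorded_barrier(self) -> Optional[float]:
        lst = self.barriers_ab + self.barriers_ba
        return min(lst) if lst else None


# ---------------------------------------------------------------------------
# Extraction


def _build_side(side: Sequence[MolecularGraph],
                reactive: Sequence[int]) -> TemplateSide:
    """Induce a template side from the reactive atoms of a reaction side."""
    reactive = sorted(reactive)
    local = {g: i for i, g in enumerate(reactive)}
    bonds = frozenset(tuple(sorted((local[a], local[b])))
                      for a, b in side_union_bonds(side)
                      if a in local and b in local)
    # fragments: connected components of the induced subgraph
    adj: list[list[int]] = [[] for _ in reactive]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    frag_of = [-1] * len(reactive)
    n_frag = 0
    for start in range(len(reactive)):
        if frag_of[start] >= 0:
            continue
        frag_of[start] = n_frag
        stack = [start]
        while stack:
            for u in adj[stack.pop()]:
                if frag_of[u] < 0:
                    frag_of[u] = n_frag
                    stack.append(u)
        n_frag += 1
    # molecule grouping, spectator molecules dropped and ids compressed
    offs = side_offsets(side)
    mol_raw = [molecule_of_atom(side, g) for g in reactive]
    mol_of_frag_raw = {}
    for i, f in enumerate(frag_of):
        mol_of_frag_raw[f] = mol_raw[i]
    mol_ids = sorted(set(mol_of_frag_raw.values()))
    compress = {m: k for k, m in enumerate(mol_ids)}
    atoms = []
    charges = []
    for g in reactive:
        m = molecule_of_atom(side, g)
        mol = side[m]
        li = g - offs[m]
        atoms.append(TemplateAtom(mol.elements[li],
                                  frozenset({mol.shapes[li]})))
        charges.append(mol.formal_charges[li])
    return TemplateSide(
        atoms=tuple(atoms),
        bonds=bonds,
        fragment_of=tuple(frag_of),
        molecule_of_fragment=tuple(
            compress[mol_of_frag_raw[f]] for f in range(n_frag)),
        formal_charges=tuple(charges),
    )


def extract_template(r: MappedReaction,
                     label: Optional[str] = None) -> ReactionTemplate:
    """Extract the reaction template of an atom-mapped reaction.

    Template atoms are exactly the endpoints of formed or broken bonds on
    each side; fragments are the connected components they induce within
    each molecule; molecules without any reactive atom are dropped.  Each
    atom's allowed-shape list starts as the singleton shape observed in the
    source reaction, and the reaction's recorded barriers are attached.

    Raises :class:`DegenerateReactionError` for a no-change reaction and
    :class:`TemplateError` for an invalid reaction record.
    """
    issues = validate(r)
    if issues:
        raise TemplateError("invalid reaction: " + "; ".join(issues))
    changes = detect_bond_changes(r)
    if changes.is_degenerate:
        raise DegenerateReactionError(
            "reaction has no bond changes; nothing to extract")
    reactive_a = sorted(changes.reactive_atoms)
    reactive_b = sorted(r.atom_map[i] for i in reactive_a)
    side_a = _build_side(r.lhs, reactive_a)
    side_b = _build_side(r.rhs, reactive_b)
    pos_b = {g: i for i, g in enumerate(reactive_b)}
    cross = tuple(pos_b[r.atom_map[g]] for g in reactive_a)
    return ReactionTemplate(
        side_a=side_a, side_b=side_b, cross_map=cross,
        barriers_ab=() if r.barrier_fwd is None else (r.barrier_fwd,),
        barriers_ba=() if r.barrier_bwd is None else (r.barrier_bwd,),
        occurrence_count=1, label=label,
    )


# ---------------------------------------------------------------------------
# Template graph & isomorphism


def build_template_graph(t: ReactionTemplate, side_tags: bool = False,
                         shape_labels: bool = True) -> nx.Graph:
    """The combined labeled graph on which template identity is decided.

    Nodes: atoms (element + allowed shapes), fragments, molecules; edges:
    containment (atom->fragment->molecule, two forests), the cross-side
    atom mapping (a perfect matching), and bonds, labeled "changed" when
    the bond does not survive to the other side.  With ``side_tags`` the
    side membership enters the node labels (used to test one fixed
    orientation at a time); deterministic by construction.
    """
    g = nx.Graph()
    changed_a = t.broken
    inv = {j: i for i, j in enumerate(t.cross_map)}
    changed_b = frozenset(
        tuple(sorted((t.cross_map[a], t.cross_map[b]))) for a, b in changed_a)
    # formed bonds exist on side b only
    formed_b = frozenset(
        tuple(sorted((t.cross_map[a], t.cross_map[b]))) for a, b in t.formed)
    changed_b = changed_b | formed_b

    for tag, side, changed in (("a", t.side_a, t.broken),
                               ("b", t.side_b, changed_b)):
        stag = tag if side_tags else ""
        for i, atom in enumerate(side.atoms):
            shapes = tuple(sorted(atom.allowed_shapes)) if shape_labels else ()
            g.add_node((tag, "atom", i), kind="atom", element=atom.element,
                       shapes=shapes, side=stag)
        for f in range(side.n_fragments):
            g.add_node((tag, "frag", f), kind="fragment", element="",
                       shapes=(), side=stag)
        for m in range(side.n_molecules):
            g.add_node((tag, "mol", m), kind="molecule", element="",
                       shapes=(), side=stag)
        for i, f in enumerate(side.fragment_of):
            g.add_edge((tag, "atom", i), (tag, "frag", f), kind="containment")
        for f, m in enumerate(side.molecule_of_fragment):
            g.add_edge((tag, "frag", f), (tag, "mol", m), kind="containment")
        for a, b in side.bonds:
            g.add_edge((tag, "atom", a), (tag, "atom", b),
                       kind="changed" if (a, b) in changed else "bond")
    for i, j in enumerate(t.cross_map):
        g.add_edge(("a", "atom", i), ("b", "atom", j), kind="map")
    return g


def _tg_node_match(shape_strict: bool):
    if shape_strict:
        def nm(x, y):
            return (x["kind"] == y["kind"] and x["element"] == y["element"]
                    and x["shapes"] == y["shapes"] and x["side"] == y["side"])
    else:
        def nm(x, y):
            return (x["kind"] == y["kind"] and x["element"] == y["element"]
                    and x["side"] == y["side"])
    return nm


def _tg_edge_match(x, y):
    return x["kind"] == y["kind"]


def reverse_template(t: ReactionTemplate) -> ReactionTemplate:
    """The template read in the opposite direction (sides swapped)."""
    inv = [0] * len(t.cross_map)
    for i, j in enumerate(t.cross_map):
        inv[j] = i
    return ReactionTemplate(
        side_a=t.side_b, side_b=t.side_a, cross_map=tuple(inv),
        barriers_ab=t.barriers_ba, barriers_ba=t.barriers_ab,
        occurrence_count=t.occurrence_count, label=t.label,
    )


def find_isomorphism(
    t1: ReactionTemplate, t2: ReactionTemplate, shape_strict: bool = True
) -> Optional[tuple[bool, dict[tuple[str, int], tuple[str, int]]]]:
    """Find a template-graph isomorphism of *t1* onto *t2*.

    Both orientations are tried.  Returns ``(reversed, atom_mapping)`` where
    ``atom_mapping`` sends ``(side, index)`` atoms of *t1* to atoms of *t2*
    in t2's original orientation, or ``None`` if the templates differ.
    """
    g1 = build_template_graph(t1, side_tags=True, shape_labels=shape_strict)
    for rev, t2o in ((False, t2), (True, reverse_template(t2))):
        g2 = build_template_graph(t2o, side_tags=True,
                                  shape_labels=shape_strict)
        gm = nx.isomorphism.GraphMatcher(
            g1, g2, node_match=_tg_node_match(shape_strict),
            edge_match=_tg_edge_match)
        if gm.is_isomorphic():
            mapping: dict[tuple[str, int], tuple[str, int]] = {}
            for n1, n2 in gm.mapping.items():
                if n1[1] != "atom":
                    continue
                side2, _, idx2 = n2
                if rev:
                    side2 = "b" if side2 == "a" else "a"
                mapping[(n1[0], n1[2])] = (side2, idx2)
            return rev, mapping
    return None


def templates_isomorphic(t1: ReactionTemplate, t2: ReactionTemplate,
                         shape_strict: bool = True) -> bool:
    """Exact template identity (side roles may swap).

    With ``shape_strict`` the allowed-shape lists must be equal as sets;
    the shape-agnostic variant (used to trigger merging) ignores them.
    """
    return find_isomorphism(t1, t2, shape_strict=shape_strict) is not None


# ---------------------------------------------------------------------------
# Merging & deduplication


def _merge_side_shapes(side: TemplateSide, extra: dict[int, frozenset[str]]
                       ) -> TemplateSide:
    atoms = tuple(
        TemplateAtom(a.element, a.allowed_shapes | extra.get(i, frozenset()))
        for i, a in enumerate(side.atoms))
    return replace(side, atoms=atoms)


def merge(t1: ReactionTemplate, t2: ReactionTemplate) -> ReactionTemplate:
    """Merge a duplicate template into another.

    Requires shape-agnostic isomorphism; allowed-shape lists are united
    atom-wise along the isomorphism, barrier lists concatenated respecting
    the matched orientation, and occurrence counts summed.
    """
    iso = find_isomorphism(t1, t2, shape_strict=False)
    if iso is None:
        raise TemplateError("cannot merge: templates are not duplicates")
    rev, mapping = iso
    extra_a: dict[int, frozenset[str]] = {}
    extra_b: dict[int, frozenset[str]] = {}
    for (s1, i1), (s2, i2) in mapping.items():
        src = t2.side_a if s2 == "a" else t2.side_b
        dst = extra_a if s1 == "a" else extra_b
        dst[i1] = src.atoms[i2].allowed_shapes
    ab2, ba2 = ((t2.barriers_ba, t2.barriers_ab) if rev
                else (t2.barriers_ab, t2.barriers_ba))
    return ReactionTemplate(
        side_a=_merge_side_shapes(t1.side_a, extra_a),
        side_b=_merge_side_shapes(t1.side_b, extra_b),
        cross_map=t1.cross_map,
        barriers_ab=t1.barriers_ab + ab2,
        barriers_ba=t1.barriers_ba + ba2,
        occurrence_count=t1.occurrence_count + t2.occurrence_count,
        label=t1.label or t2.label,
    )


class TemplateLibrary:
    """An indexable, serializable collection of deduplicated templates."""

    def __init__(self, templates: Iterable[ReactionTemplate] = ()):
        self.templates: list[ReactionTemplate] = list(templates)

    def __len__(self) -> int:
        return len(self.templates)

    def __getitem__(self, i: int) -> ReactionTemplate:
        return self.templates[i]

    def __iter__(self):
        return iter(self.templates)

    def add(self, t: ReactionTemplate) -> int:
        """Merge *t* into the first duplicate entry, else append.

        Returns the index of the entry that absorbed the template.
        """
        for i, existing in enumerate(self.templates):
            if templates_isomorphic(existing, t, shape_strict=False):
                self.templates[i] = merge(existing, t)
                return i
        self.templates.append(t)
        return len(self.templates) - 1

    def find(self, t: ReactionTemplate) -> Optional[int]:
        """Index of the shape-agnostic duplicate of *t*, if any."""
        for i, existing in enumerate(self.templates):
            if templates_isomorphic(existing, t, shape_strict=False):
                return i
        return None

    def to_json(self) -> str:
        return json.dumps(
            {"schema": "rxntemplates/template-library/1",
             "templates": [_template_to_record(t) for t in self.templates]},
            indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TemplateLibrary":
        doc = json.loads(text)
        if doc.get("schema") != "rxntemplates/template-library/1":
            raise TemplateError(
                f"unsupported template library schema: {doc.get('schema')!r}")
        return cls(_template_from_record(r) for r in doc["templates"])


def deduplicate(templates: Iterable[ReactionTemplate]) -> TemplateLibrary:
    """Greedy pass merging isomorphic templates; order-independent up to
    isomorphism of the resulting entries."""
    lib = TemplateLibrary()
    for t in templates:
        lib.add(t)
    return lib


# ---------------------------------------------------------------------------
# Graph edit distance


def _ged_graphs(t: ReactionTemplate) -> nx.Graph:
    return build_template_graph(t, side_tags=False, shape_labels=True)


def template_ged(t1: ReactionTemplate, t2: ReactionTemplate,
                 exact_max_total_nodes: int = GED_EXACT_MAX_TOTAL_NODES
                 ) -> float:
    """Graph edit distance between two template graphs, unit costs.

    Strictly identical templates are recognized by isomorphism and give an
    exact 0 at any size.  Otherwise an exact edit-path search runs when the
    two graphs together have at most ``exact_max_total_nodes`` nodes; for
    larger pairs an assignment-style upper bound is returned (the smaller
    of both argument orders, so the result stays symmetric) and an
    :class:`ApproximateGEDWarning` is emitted.
    """
    if templates_isomorphic(t1, t2, shape_strict=True):
        return 0.0
    g1, g2 = _ged_graphs(t1), _ged_graphs(t2)
    nm = _tg_node_match(True)
    em = _tg_edge_match
    total = g1.number_of_nodes() + g2.number_of_nodes()
    if total <= exact_max_total_nodes:
        return float(nx.graph_edit_distance(g1, g2, node_match=nm,
                                            edge_match=em))
    warnings.warn("template graphs exceed the exact-search size; returning "
                  "an upper bound on the edit distance",
                  ApproximateGEDWarning, stacklevel=2)
    b1 = next(nx.optimize_graph_edit_distance(g1, g2, node_match=nm,
                                              edge_match=em))
    b2 = next(nx.optimize_graph_edit_distance(g2, g1, node_match=nm,
                                              edge_match=em))
    return float(min(b1, b2))


def ged_matrix(library: TemplateLibrary) -> tuple[np.ndarray, list[int]]:
    """Pairwise template GEDs, rows ordered by minimal recorded barrier.

    Returns ``(matrix, order)`` where ``order[k]`` is the library index in
    row/column ``k`` (ascending minimal barrier; barrier-free templates
    last, original order preserved among ties).
    """
    def key(i: int):
        b = library[i].min_recorded_barrier()
        return (b is None, b if b is not None else 0.0, i)

    order = sorted(range(len(library)), key=key)
    n = len(order)
    mat = np.zeros((n, n))
    for p in range(n):
        for q in range(p + 1, n):
            d = template_ged(library[order[p]], library[order[q]])
            mat[p, q] = mat[q, p] = d
    return mat, order


# ---------------------------------------------------------------------------
# Occurrence / barrier spectrum


@dataclass
class SpectrumEntry:
    """Occurrence statistics of one template within a reaction set."""

    index: int
    template: ReactionTemplate
    count: int = 0
    barriers: list = field(default_factory=list)          # forward (a->b)
    barriers_reverse: list = field(default_factory=list)  # observed b->a

    @property
    def min_barrier(self) -> Optional[float]:
        return min(self.barriers) if self.barriers else None


@dataclass
class Spectrum:
    """Per-template occurrence counts and recorded barriers for a network."""

    entries: list[SpectrumEntry]
    new_templates: TemplateLibrary


def barrier_spectrum(library: TemplateLibrary,
                     reactions: Iterable[MappedReaction]) -> Spectrum:
    """Group reactions by library template and tally occurrences/barriers.

    Each reaction is re-extracted and assigned to its (shape-agnostic)
    duplicate in the library; reactions without a matching entry are
    deduplicated into a separate library of new templates.  Entries come
    back sorted by minimal recorded forward barrier (unknown barriers
    last).
    """
    entries = {i: SpectrumEntry(i, t) for i, t in enumerate(library)}
    new = TemplateLibrary()
    for r in reactions:
        t = extract_template(r)
        idx = library.find(t)
        if idx is None:
            j = new.add(t)
            continue
        iso = find_isomorphism(library[idx], t, shape_strict=False)
        rev = iso[0]
        e = entries[idx]
        e.count += 1
        if r.barrier_fwd is not None:
            (e.barriers_reverse if rev else e.barriers).append(r.barrier_fwd)
        if r.barrier_bwd is not None:
            (e.barriers if rev else e.barriers_reverse).append(r.barrier_bwd)
    occupied = [e for e in entries.values() if e.count]
    occupied.sort(key=lambda e: (e.min_barrier is None,
                                 e.min_barrier or 0.0, e.index))
    return Spectrum(entries=occupied, new_templates=new)


# ---------------------------------------------------------------------------
# Serialization & DOT export


def _side_to_record(s: TemplateSide) -> dict:
    return {
        "atoms": [{"element": a.element,
                   "shapes": sorted(a.allowed_shapes)} for a in s.atoms],
        "bonds": sorted([a, b] for a, b in s.bonds),
        "fragment_of": list(s.fragment_of),
        "molecule_of_fragment": list(s.molecule_of_fragment),
        "formal_charges": list(s.formal_charges),
    }


def _side_from_record(rec: dict) -> TemplateSide:
    return TemplateSide(
        atoms=tuple(TemplateAtom(a["element"], frozenset(a["shapes"]))
                    for a in rec["atoms"]),
        bonds=frozenset(tuple(sorted((a, b))) for a, b in rec["bonds"]),
        fragment_of=tuple(rec["fragment_of"]),
        molecule_of_fragment=tuple(rec["molecule_of_fragment"]),
        formal_charges=tuple(rec["formal_charges"]),
    )


def _template_to_record(t: ReactionTemplate) -> dict:
    return {
        "side_a": _side_to_record(t.side_a),
        "side_b": _side_to_record(t.side_b),
        "cross_map": list(t.cross_map),
        "barriers_ab": list(t.barriers_ab),
        "barriers_ba": list(t.barriers_ba),
        "occurrence_count": t.occurrence_count,
        "label": t.label,
    }


def _template_from_record(rec: dict) -> ReactionTemplate:
    return ReactionTemplate(
        side_a=_side_from_record(rec["side_a"]),
        side_b=_side_from_record(rec["side_b"]),
        cross_map=tuple(rec["cross_map"]),
        barriers_ab=tuple(rec["barriers_ab"]),
        barriers_ba=tuple(rec["barriers_ba"]),
        occurrence_count=rec["occurrence_count"],
        label=rec.get("label"),
    )


def template_to_dot(t: ReactionTemplate) -> str:
    """Graphviz DOT rendering of the combined template graph.

    Atom nodes are ellipses labeled element/shapes, fragment and molecule
    nodes are boxes; broken bonds red, formed bonds green, unchanged bonds
    black, the cross-side mapping dashed gray, containment dotted.
    """
    g = build_template_graph(t, side_tags=True)
    lines = ["graph template {"]
    for n, attrs in g.nodes(data=True):
        name = f'"{n[0]}_{n[1]}_{n[2]}"'
        if attrs["kind"] == "atom":
            label = attrs["element"]
            if attrs["shapes"]:
                label += "\\n" + ",".join(attrs["shapes"])
            lines.append(f"  {name} [shape=ellipse, label=\"{label}\"];")
        else:
            lines.append(f"  {name} [shape=box, label=\"{n[1]}{n[2]}\"];")
    broken_a = t.broken
    formed_b = {tuple(sorted((t.cross_map[a], t.cross_map[b])))
                for a, b in t.formed}
    for u, v, attrs in g.edges(data=True):
        nu, nv = (f'"{u[0]}_{u[1]}_{u[2]}"', f'"{v[0]}_{v[1]}_{v[2]}"')
        kind = attrs["kind"]
        if kind == "map":
            style = "[style=dashed, color=gray]"
        elif kind == "containment":
            style = "[style=dotted]"
        else:
            pair = tuple(sorted((u[2], v[2])))
            if u[0] == "a" and pair in broken_a:
                style = "[color=red]"
            elif u[0] == "b" and pair in formed_b:
                style = "[color=green]"
            else:
                style = "[color=black]"
        lines.append(f"  {nu} -- {nv} {style};")
    lines.append("}")
    return "\n".join(lines)
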