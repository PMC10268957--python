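"""Molecular graphs with annotated atoms, plus isomorphism primitives.

A molecule is a graph of atoms (nodes carrying the element symbol, a local
coordination-shape label and an optional stereo descriptor) and binary bonds
(an edge either exists or it does not; bond orders are deliberately not
stored).  This module provides construction, shape assignment, connected
component splitting, exact isomorphism, subgraph-embedding enumeration for
template fragments, and a canonical key that defines compound identity.

The stereo model is minimal: a per-atom descriptor in {None, "A", "B"}
distinguishing the two arrangements at a center with four distinct
branches.  It is a deliberate stand-in for full stereopermutator bookkeeping
and is sufficient to enumerate enantiomeric products during template
application.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx

from .canonical import canonical_certificate
from .elements import DEFAULT_VALENCES, atomic_mass, is_element

__all__ = [
    "Atom",
    "MolecularGraph",
    "Fragment",
    "Embedding",
    "GraphError",
    "build_graph",
    "assign_shapes",
    "shape_for_degree",
    "connected_components",
    "split_components",
    "is_isomorphic",
    "subgraph_embeddings",
    "canonical_key",
    "molecular_formula",
]

Bond = tuple[int, int]

# Local coordination shapes, keyed by the number of bonded neighbors.  The
# taxonomy is a deterministic stand-in for a full 3D shape classifier: it is
# a pure function of element-agnostic degree, except that a degree-2 atom
# may be flagged linear by the caller (e.g. an sp carbon).
_SHAPE_BY_DEGREE = {0: "isolated", 1: "terminal", 2: "bent",
                    3: "trigonal planar", 4: "tetrahedron"}


def shape_for_degree(degree: int, linear: bool = False) -> str:
    if degree == 2 and linear:
        return "linear"
    if degree in _SHAPE_BY_DEGREE:
        return _SHAPE_BY_DEGREE[degree]
    return f"other({degree})"


class GraphError(ValueError):
    """Raised for structurally invalid molecular-graph input."""


@dataclass(frozen=True)
class Atom:
    """One atom of a molecular graph."""

    index: int
    element: str
    shape: str = "isolated"
    stereo: Optional[str] = None

    def __post_init__(self):
        if self.stereo not in (None, "A", "B"):
            raise GraphError(f"atom {self.index}: invalid stereo descriptor "
                             f"{self.stereo!r} (expected None, 'A' or 'B')")


def _norm_bond(i: int, j: int) -> Bond:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class MolecularGraph:
    """An immutable molecular graph.

    ``formal_charges`` attribute per-atom integer charges summing to
    ``charge``; they are bookkeeping for splitting the total charge over
    product molecules and are *not* part of compound identity.
    """

    elements: tuple[str, ...]
    bonds: frozenset[Bond]
    charge: int = 0
    shapes: tuple[str, ...] = ()
    stereo: tuple[Optional[str], ...] = ()
    formal_charges: tuple[int, ...] = ()

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atoms(self) -> list[Atom]:
        return [Atom(i, self.elements[i], self.shapes[i], self.stereo[i])
                for i in range(self.n_atoms)]

    @property
    def mass(self) -> float:
        """Sum of standard atomic weights (u)."""
        return sum(atomic_mass(e) for e in self.elements)

    def degree(self, i: int) -> int:
        return sum(1 for b in self.bonds if i in b)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for a, b in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i in range(self.n_atoms):
            g.add_node(i, element=self.elements[i], shape=self.shapes[i],
                       stereo=self.stereo[i])
        g.add_edges_from(self.bonds)
        return g

    def with_stereo(self, stereo: Sequence[Optional[str]]) -> "MolecularGraph":
        return replace(self, stereo=tuple(stereo))

    def is_connected(self) -> bool:
        if self.n_atoms <= 1:
            return True
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for u in adj[stack.pop()]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        return len(seen) == self.n_atoms


@dataclass(frozen=True)
class Fragment:
    """A connected template fragment used as a subgraph-matching pattern.

    Each pattern atom carries the element and the set of local shapes it is
    allowed to sit on in a host molecule.
    """

    elements: tuple[str, ...]
    allowed_shapes: tuple[frozenset[str], ...]
    bonds: frozenset[Bond] = field(default_factory=frozenset)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i in range(self.n_atoms):
            g.add_node(i, element=self.elements[i],
                       allowed=self.allowed_shapes[i])
        g.add_edges_from(self.bonds)
        return g


@dataclass(frozen=True)
class Embedding:
    """An injective, label-compatible placement of a fragment in a host."""

    mapping: tuple[tuple[int, int], ...]  # (pattern atom -> host atom)

    @property
    def as_dict(self) -> dict[int, int]:
        return dict(self.mapping)

    @property
    def host_atoms(self) -> frozenset[int]:
        return frozenset(h for _, h in self.mapping)


def _default_formal_charges(elements, bonds, charge) -> tuple[int, ...]:
    """Place a nonzero total charge on the most valence-deficient atom.

    A heuristic fallback for inputs without explicit per-atom charges; the
    anionic species handled here (alkoxides, halides, hydride) all resolve
    to the chemically expected atom.
    """
    n = len(elements)
    if charge == 0:
        return (0,) * n
    degs = [0] * n
    for a, b in bonds:
        degs[a] += 1
        degs[b] += 1
    deficiency = [degs[i] - DEFAULT_VALENCES.get(elements[i], degs[i])
                  for i in range(n)]
    target = min(range(n), key=lambda i: (deficiency[i], i))
    out = [0] * n
    out[target] = charge
    return tuple(out)


def build_graph(
    elements: Sequence[str],
    bonds: Iterable[Sequence[int]],
    charge: int = 0,
    stereo: Optional[Sequence[Optional[str]]] = None,
    formal_charges: Optional[Sequence[int]] = None,
    linear_atoms: Iterable[int] = (),
) -> MolecularGraph:
    """Construct a molecular graph and assign local shapes.

    Parameters
    ----------
    elements : element symbols, 0-indexed.
    bonds : iterable of (i, j) index pairs; binary bonds, undirected.
    charge : total molecular charge.
    stereo : optional per-atom stereo descriptors (None/"A"/"B").
    formal_charges : optional per-atom charges summing to ``charge``.
    linear_atoms : degree-2 atoms to label "linear" instead of "bent".

    Raises
    ------
    GraphError for unknown elements, self-loops, duplicate or out-of-range
    bonds, or inconsistent formal charges.
    """
    elements = tuple(elements)
    if not elements:
        raise GraphError("a molecular graph needs at least one atom")
    for i, e in enumerate(elements):
        if not is_element(e):
            raise GraphError(f"atom {i}: invalid element symbol {e!r}")
    n = len(elements)
    seen: set[Bond] = set()
    for pair in bonds:
        i, j = int(pair[0]), int(pair[1])
        if i == j:
            raise GraphError(f"self-loop bond ({i}, {j}) is not allowed")
        if not (0 <= i < n and 0 <= j < n):
            raise GraphError(f"bond ({i}, {j}) references a missing atom "
                             f"(graph has {n} atoms)")
        b = _norm_bond(i, j)
        if b in seen:
            raise GraphError(f"duplicate bond {b}")
        seen.add(b)
    bondset = frozenset(seen)
    if stereo is None:
        stereo_t: tuple[Optional[str], ...] = (None,) * n
    else:
        if len(stereo) != n:
            raise GraphError("stereo list length does not match atom count")
        stereo_t = tuple(stereo)
    for i, s in enumerate(stereo_t):
        if s not in (None, "A", "B"):
            raise GraphError(f"atom {i}: invalid stereo descriptor {s!r}")
    if formal_charges is None:
        fcs = _default_formal_charges(elements, bondset, charge)
    else:
        fcs = tuple(int(c) for c in formal_charges)
        if len(fcs) != n:
            raise GraphError("formal_charges length does not match atom count")
        if sum(fcs) != charge:
            raise GraphError(f"formal charges sum to {sum(fcs)}, "
                             f"declared total charge is {charge}")
    g = MolecularGraph(elements=elements, bonds=bondset, charge=charge,
                       shapes=("isolated",) * n, stereo=stereo_t,
                       formal_charges=fcs)
    return assign_shapes(g, linear_atoms=linear_atoms)


def assign_shapes(g: MolecularGraph,
                  linear_atoms: Iterable[int] = ()) -> MolecularGraph:
    """Assign each atom's local shape from its bonded-neighbor count.

    Idempotent; degrees outside the lookup table yield ``other(k)`` labels
    rather than an error.
    """
    linear = set(linear_atoms)
    shapes = tuple(shape_for_degree(g.degree(i), linear=i in linear)
                   for i in range(g.n_atoms))
    return replace(g, shapes=shapes)


def split_components(
    g: MolecularGraph, charges: Optional[Sequence[int]] = None
) -> tuple[list[MolecularGraph], list[list[int]]]:
    """Split a (possibly multi-molecule) graph into connected components.

    Returns the component graphs and, for each, the list of original atom
    indices (component-local index -> original index).  Component charges
    are taken from *charges* if given (one per component, in output order),
    else from the per-atom formal charges.
    """
    if g.n_atoms == 0:
        return [], []
    adj = g.adjacency()
    comp_of = [-1] * g.n_atoms
    comps: list[list[int]] = []
    for start in range(g.n_atoms):
        if comp_of[start] >= 0:
            continue
        comp = [start]
        comp_of[start] = len(comps)
        stack = [start]
        while stack:
            for u in adj[stack.pop()]:
                if comp_of[u] < 0:
                    comp_of[u] = len(comps)
                    comp.append(u)
                    stack.append(u)
        comps.append(sorted(comp))
    if charges is not None and len(charges) != len(comps):
        raise GraphError(f"{len(charges)} component charges supplied for "
                         f"{len(comps)} components")
    out = []
    for k, comp in enumerate(comps):
        local = {orig: i for i, orig in enumerate(comp)}
        fcs = tuple(g.formal_charges[orig] for orig in comp)
        chg = charges[k] if charges is not None else sum(fcs)
        if charges is not None and sum(fcs) != chg:
            fcs = _default_formal_charges(
                tuple(g.elements[orig] for orig in comp),
                frozenset(_norm_bond(local[a], local[b]) for a, b in g.bonds
                          if a in local and b in local),
                chg)
        sub = MolecularGraph(
            elements=tuple(g.elements[orig] for orig in comp),
            bonds=frozenset(_norm_bond(local[a], local[b])
                            for a, b in g.bonds if a in local and b in local),
            charge=chg,
            shapes=tuple(g.shapes[orig] for orig in comp),
            stereo=tuple(g.stereo[orig] for orig in comp),
            formal_charges=fcs,
        )
        out.append(assign_shapes(sub))
    return out, comps


def connected_components(
    g: MolecularGraph, charges: Optional[Sequence[int]] = None
) -> list[MolecularGraph]:
    """Partition a multi-molecule atom set into individual molecules."""
    return split_components(g, charges)[0]


def molecular_formula(g: MolecularGraph) -> str:
    counts = Counter(g.elements)
    return "".join(f"{e}{counts[e]}" for e in sorted(counts))


def _node_match(a: dict, b: dict) -> bool:
    return a["element"] == b["element"] and a["stereo"] == b["stereo"]


def is_isomorphic(g1: MolecularGraph, g2: MolecularGraph) -> bool:
    """Exact isomorphism respecting elements, stereo descriptors and charge."""
    if g1.charge != g2.charge or g1.n_atoms != g2.n_atoms:
        return False
    if Counter(g1.elements) != Counter(g2.elements):
        return False
    if len(g1.bonds) != len(g2.bonds):
        return False
    return nx.is_isomorphic(g1.to_networkx(), g2.to_networkx(),
                            node_match=_node_match)


def _pattern_automorphisms(pattern: Fragment) -> list[dict[int, int]]:
    pg = pattern.to_networkx()
    gm = nx.isomorphism.GraphMatcher(
        pg, pg,
        node_match=lambda a, b: (a["element"] == b["element"]
                                 and a["allowed"] == b["allowed"]))
    return [dict(m) for m in gm.isomorphisms_iter()]


def subgraph_embeddings(pattern: Fragment,
                        host: MolecularGraph) -> list[Embedding]:
    """All label-compatible embeddings of a template fragment in a host.

    An embedding is an injective map such that elements match, the host
    atom's shape is in the pattern atom's allowed-shape list, and every
    pattern bond maps onto a host bond (a monomorphism: extra host bonds
    between matched atoms are permitted).  Embeddings that coincide up to an
    automorphism of the pattern are collapsed; results are sorted by the
    mapped host index tuple.
    """
    if pattern.n_atoms > host.n_atoms:
        return []
    hg = host.to_networkx()
    pg = pattern.to_networkx()

    def compatible(host_attrs: dict, pat_attrs: dict) -> bool:
        return (host_attrs["element"] == pat_attrs["element"]
                and host_attrs["shape"] in pat_attrs["allowed"])

    gm = nx.isomorphism.GraphMatcher(hg, pg, node_match=compatible)
    autos = _pattern_automorphisms(pattern)
    seen: set[tuple[int, ...]] = set()
    found: list[Embedding] = []
    for m in gm.subgraph_monomorphisms_iter():
        emb = {p: h for h, p in m.items()}
        rep = min(tuple(emb[a[p]] for p in range(pattern.n_atoms))
                  for a in autos)
        if rep in seen:
            continue
        seen.add(rep)
        found.append(Embedding(tuple(sorted(emb.items()))))
    found.sort(key=lambda e: tuple(h for _, h in e.mapping))
    return found


def _reduced_for_key(g: MolecularGraph):
    """Fold plain terminal hydrogens into their heavy atom's label.

    Degree-1 H atoms without stereo descriptors bonded to a non-H atom are
    removed and counted in the neighbor's label; this keeps the canonical
    search tree small for organic graphs while preserving isomorphism
    classes exactly.
    """
    n = g.n_atoms
    adj = g.adjacency()
    folded: dict[int, int] = {}
    keep: list[int] = []
    for i in range(n):
        if (g.elements[i] == "H" and g.stereo[i] is None and len(adj[i]) == 1
                and g.elements[adj[i][0]] != "H"):
            heavy = adj[i][0]
            folded[heavy] = folded.get(heavy, 0) + 1
        else:
            keep.append(i)
    local = {orig: k for k, orig in enumerate(keep)}
    radj: list[list[int]] = [[] for _ in keep]
    for a, b in g.bonds:
        if a in local and b in local:
            radj[local[a]].append(local[b])
            radj[local[b]].append(local[a])
    labels = [(g.elements[orig], g.stereo[orig], folded.get(orig, 0))
              for orig in keep]
    return radj, labels


def canonical_key(g: MolecularGraph) -> str:
    """Canonical compound key: equal keys exactly for isomorphic graphs.

    Includes the total charge and the stereo descriptors; formal-charge
    bookkeeping and shape labels (derivable from connectivity) are excluded.
    """
    radj, labels = _reduced_for_key(g)
    cert = canonical_certificate(radj, labels)
    digest = hashlib.sha1(
        f"{cert}|charge={g.charge}".encode()).hexdigest()[:16]
    return f"{molecular_formula(g)}{g.charge:+d}:{digest}"
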