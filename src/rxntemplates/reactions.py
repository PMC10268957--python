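"""Atom-mapped reaction records and bond-change detection.

A :class:`MappedReaction` holds the reactant- and product-side molecular
graphs together with a bijective atom map between the two sides.  Atoms are
addressed by *global* per-side indices: the atoms of the i-th molecule are
offset by the sizes of molecules 0..i-1, which makes multi-molecule
reactions unambiguous.  Optional energies are free-energy-like scalars in
kJ/mol attached as given by the data source; no thermochemistry is
computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .molgraph import MolecularGraph, build_graph

__all__ = [
    "MappedReaction",
    "BondChange",
    "validate",
    "detect_bond_changes",
    "reverse",
    "DegenerateReactionError",
    "side_offsets",
    "molecule_of_atom",
    "side_union_bonds",
    "reaction_to_record",
    "reaction_from_record",
]

Pair = tuple[int, int]


class DegenerateReactionError(ValueError):
    """Raised when a reaction without any bond change reaches an operation
    that requires one (e.g. template extraction)."""


def side_offsets(side: Sequence[MolecularGraph]) -> list[int]:
    offs, total = [], 0
    for g in side:
        offs.append(total)
        total += g.n_atoms
    return offs


def molecule_of_atom(side: Sequence[MolecularGraph], global_idx: int) -> int:
    offs = side_offsets(side)
    for k in range(len(side) - 1, -1, -1):
        if global_idx >= offs[k]:
            return k
    raise IndexError(global_idx)


def side_union_bonds(side: Sequence[MolecularGraph]) -> set[Pair]:
    offs = side_offsets(side)
    bonds: set[Pair] = set()
    for off, g in zip(offs, side):
        for a, b in g.bonds:
            bonds.add((a + off, b + off))
    return bonds


def _side_elements(side: Sequence[MolecularGraph]) -> list[str]:
    out: list[str] = []
    for g in side:
        out.extend(g.elements)
    return out


@dataclass(frozen=True)
class MappedReaction:
    """A reaction with an exact atom mapping between its two sides.

    ``atom_map[i]`` is the product-side global index of reactant-side global
    atom ``i``.  ``barrier_fwd``/``barrier_bwd`` are activation energies for
    the forward/backward direction and ``reaction_energy`` the forward
    reaction energy, all in kJ/mol.
    """

    lhs: tuple[MolecularGraph, ...]
    rhs: tuple[MolecularGraph, ...]
    atom_map: tuple[int, ...]
    barrier_fwd: Optional[float] = None
    barrier_bwd: Optional[float] = None
    reaction_energy: Optional[float] = None

    @property
    def n_atoms(self) -> int:
        return sum(g.n_atoms for g in self.lhs)


@dataclass(frozen=True)
class BondChange:
    """Bonds formed and broken, both expressed on reactant-side indices."""

    formed: frozenset[Pair]
    broken: frozenset[Pair]

    @property
    def is_degenerate(self) -> bool:
        return not self.formed and not self.broken

    @property
    def reactive_atoms(self) -> frozenset[int]:
        atoms: set[int] = set()
        for a, b in self.formed | self.broken:
            atoms.update((a, b))
        return frozenset(atoms)


def validate(r: MappedReaction) -> list[str]:
    """Check reaction invariants; returns a list of violation messages.

    An empty list means the atom map is a bijection, elements are preserved
    under the map, atom counts agree, and the total charge is conserved.
    """
    issues: list[str] = []
    n_l = sum(g.n_atoms for g in r.lhs)
    n_r = sum(g.n_atoms for g in r.rhs)
    if n_l != n_r:
        issues.append(f"atom counts differ: {n_l} reactant-side vs "
                      f"{n_r} product-side atoms")
    if len(r.atom_map) != n_l:
        issues.append(f"atom map covers {len(r.atom_map)} of {n_l} atoms")
        return issues
    targets = list(r.atom_map)
    if sorted(targets) != list(range(n_r)):
        issues.append("atom map is not a bijection onto product-side atoms")
        return issues
    el_l = _side_elements(r.lhs)
    el_r = _side_elements(r.rhs)
    for i, j in enumerate(targets):
        if el_l[i] != el_r[j]:
            issues.append(f"element mismatch under map: reactant atom {i} "
                          f"({el_l[i]}) -> product atom {j} ({el_r[j]})")
    q_l = sum(g.charge for g in r.lhs)
    q_r = sum(g.charge for g in r.rhs)
    if q_l != q_r:
        issues.append(f"total charge not conserved: {q_l} -> {q_r}")
    return issues


def detect_bond_changes(r: MappedReaction) -> BondChange:
    """Classify the symmetric difference of the mapped bond sets.

    A bond is *formed* if absent between two reactant atoms but present
    between their product images, *broken* in the converse case.  A
    degenerate (no-change) reaction yields an empty
    :class:`BondChange` (``is_degenerate``) so callers can skip template
    extraction.
    """
    lhs_bonds = side_union_bonds(r.lhs)
    rhs_bonds = side_union_bonds(r.rhs)
    mapped_lhs = {tuple(sorted((r.atom_map[a], r.atom_map[b])))
                  for a, b in lhs_bonds}
    inv = {j: i for i, j in enumerate(r.atom_map)}
    formed = {tuple(sorted((inv[a], inv[b])))
              for a, b in rhs_bonds if (a, b) not in mapped_lhs}
    broken = {(a, b) for a, b in lhs_bonds
              if tuple(sorted((r.atom_map[a], r.atom_map[b]))) not in rhs_bonds}
    return BondChange(frozenset(formed), frozenset(broken))


def reverse(r: MappedReaction) -> MappedReaction:
    """Swap the two sides: barriers exchanged, reaction energy negated."""
    inv = [0] * len(r.atom_map)
    for i, j in enumerate(r.atom_map):
        inv[j] = i
    return MappedReaction(
        lhs=r.rhs, rhs=r.lhs, atom_map=tuple(inv),
        barrier_fwd=r.barrier_bwd, barrier_bwd=r.barrier_fwd,
        reaction_energy=(None if r.reaction_energy is None
                         else -r.reaction_energy),
    )


# ---------------------------------------------------------------------------
# JSON reaction records


def _molecule_to_record(g: MolecularGraph) -> dict:
    rec = {
        "elements": list(g.elements),
        "bonds": sorted([a, b] for a, b in g.bonds),
        "charge": g.charge,
    }
    if any(s is not None for s in g.stereo):
        rec["stereo"] = [s if s is not None else "" for s in g.stereo]
    if any(g.formal_charges):
        rec["formal_charges"] = list(g.formal_charges)
    return rec


def _molecule_from_record(rec: dict) -> MolecularGraph:
    stereo = None
    if "stereo" in rec:
        stereo = [s if s else None for s in rec["stereo"]]
    return build_graph(rec["elements"], rec["bonds"],
                       charge=rec.get("charge", 0), stereo=stereo,
                       formal_charges=rec.get("formal_charges"))


def reaction_to_record(r: MappedReaction) -> dict:
    """Serialize a reaction to a plain-JSON record."""
    rec = {
        "lhs": [_molecule_to_record(g) for g in r.lhs],
        "rhs": [_molecule_to_record(g) for g in r.rhs],
        "map": [[i, j] for i, j in enumerate(r.atom_map)],
    }
    barriers = {}
    if r.barrier_fwd is not None:
        barriers["fwd"] = r.barrier_fwd
    if r.barrier_bwd is not None:
        barriers["bwd"] = r.barrier_bwd
    if barriers:
        rec["barriers"] = barriers
    if r.reaction_energy is not None:
        rec["energy"] = r.reaction_energy
    return rec


def reaction_from_record(rec: dict) -> MappedReaction:
    pairs = sorted((int(i), int(j)) for i, j in rec["map"])
    atom_map = tuple(j for _, j in pairs)
    barriers = rec.get("barriers", {})
    return MappedReaction(
        lhs=tuple(_molecule_from_record(m) for m in rec["lhs"]),
        rhs=tuple(_molecule_from_record(m) for m in rec["rhs"]),
        atom_map=atom_map,
        barrier_fwd=barriers.get("fwd"),
        barrier_bwd=barriers.get("bwd"),
        reaction_energy=rec.get("energy"),
    )
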