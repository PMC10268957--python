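"""Reader for exported SCINE-style network snapshots.

Deposited exploration networks are stored in MongoDB databases following
the SCINE Database layout (structures, compounds, elementary steps,
reactions).  This adapter targets an offline JSON snapshot of those
collections rather than a live server: structures carry element lists,
bond-order lists and charges; elementary steps carry reactant/product
structure ids, an exact atom map and energies in Hartree.  Records that
cannot be converted into a valid atom-mapped reaction are skipped with a
logged reason, never silently.

Energies are converted at 1 Hartree = 2625.499639 kJ/mol; when a reaction
groups several elementary steps, the aggregated barrier per direction is
the minimum over its steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .molgraph import MolecularGraph, build_graph
from .reactions import MappedReaction, validate

__all__ = ["HARTREE_TO_KJMOL", "AdapterResult", "load_network",
           "structure_to_graph"]

HARTREE_TO_KJMOL = 2625.499639


@dataclass
class AdapterResult:
    """Converted reactions plus bookkeeping about what was skipped."""

    reactions: list[MappedReaction] = field(default_factory=list)
    step_ids: list[str] = field(default_factory=list)
    compounds: dict[str, MolecularGraph] = field(default_factory=dict)
    reaction_groups: dict[str, dict] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def structure_to_graph(rec: dict) -> MolecularGraph:
    """Build a molecular graph from a structure record.

    Bond entries are ``[i, j, order]``; an edge exists when the reported
    bond order is at least 0.5.
    """
    bonds = [(int(i), int(j)) for i, j, order in rec["bonds"]
             if float(order) >= 0.5]
    return build_graph(rec["elements"], bonds, charge=rec.get("charge", 0),
                       formal_charges=rec.get("formal_charges"))


def _step_to_reaction(step: dict, structures: dict) -> MappedReaction:
    lhs = tuple(structure_to_graph(structures[s]) for s in step["reactants"])
    rhs = tuple(structure_to_graph(structures[s]) for s in step["products"])
    if "atom_map" not in step:
        raise KeyError("missing atom map")
    pairs = sorted((int(i), int(j)) for i, j in step["atom_map"])
    atom_map = tuple(j for _, j in pairs)
    en = step.get("energies", {})
    barrier_fwd = barrier_bwd = energy = None
    if {"reactant", "ts", "product"} <= en.keys():
        barrier_fwd = (en["ts"] - en["reactant"]) * HARTREE_TO_KJMOL
        barrier_bwd = (en["ts"] - en["product"]) * HARTREE_TO_KJMOL
        energy = (en["product"] - en["reactant"]) * HARTREE_TO_KJMOL
    r = MappedReaction(lhs=lhs, rhs=rhs, atom_map=atom_map,
                       barrier_fwd=barrier_fwd, barrier_bwd=barrier_bwd,
                       reaction_energy=energy)
    issues = validate(r)
    if issues:
        raise ValueError("; ".join(issues))
    return r


def load_network(path: Union[str, Path],
                 options: Optional[dict] = None) -> AdapterResult:
    """Load a JSON network snapshot into atom-mapped reaction records.

    Returns an :class:`AdapterResult` with one reaction per convertible
    elementary step, the compound table, per-reaction aggregated barriers
    (minimum per direction over the grouped steps), and the list of
    ``(record id, reason)`` pairs that were skipped.
    """
    doc = json.loads(Path(path).read_text())
    if not str(doc.get("format", "")).startswith("scine-db-export"):
        raise ValueError(f"unrecognized export format: {doc.get('format')!r}")
    structures = doc.get("structures", {})
    result = AdapterResult()
    step_index: dict[str, int] = {}
    for sid, step in sorted(doc.get("elementary_steps", {}).items()):
        try:
            r = _step_to_reaction(step, structures)
        except (KeyError, ValueError) as exc:
            result.skipped.append((sid, str(exc)))
            continue
        step_index[sid] = len(result.reactions)
        result.reactions.append(r)
        result.step_ids.append(sid)
    for cid, comp in sorted(doc.get("compounds", {}).items()):
        sids = comp.get("structures", [])
        if sids and sids[0] in structures:
            result.compounds[cid] = structure_to_graph(structures[sids[0]])
    for rid, rxn in sorted(doc.get("reactions", {}).items()):
        steps = [s for s in rxn.get("steps", []) if s in step_index]
        fwd = [result.reactions[step_index[s]].barrier_fwd for s in steps]
        bwd = [result.reactions[step_index[s]].barrier_bwd for s in steps]
        result.reaction_groups[rid] = {
            "steps": steps,
            "lhs_compounds": rxn.get("lhs_compounds", []),
            "rhs_compounds": rxn.get("rhs_compounds", []),
            "barrier_fwd": min((b for b in fwd if b is not None),
                               default=None),
            "barrier_bwd": min((b for b in bwd if b is not None),
                               default=None),
        }
    return result
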