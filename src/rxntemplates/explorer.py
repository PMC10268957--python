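"""Template-filtered reaction-network exploration with a surrogate step
oracle.

The explorer grows a network of compounds and reactions generation by
generation: every active compound (and every unordered pair of active
compounds whose charges do not share a sign) is matched against a template
library; matches whose template direction has a recorded barrier below the
application threshold become reaction trials; a pluggable *step oracle*
stands in for the elementary-step search plus electronic-structure layer
and returns barrier/reaction-energy pairs for the products of a trial.
Products below the mass cap are registered as compounds, the reactions
recorded, and compound activity re-propagated: a compound is active when it
is reachable from the seed compounds through reactions whose barrier and
reaction energy lie strictly below the configured thresholds.

Everything is deterministic given the inputs and the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .matching import Trial, apply_match, enumerate_trials
from .molgraph import MolecularGraph, canonical_key
from .reactions import MappedReaction, reaction_from_record, reaction_to_record
from .templates import TemplateLibrary

__all__ = [
    "Compound",
    "ReactionRecord",
    "ExplorationConfig",
    "Network",
    "charge_pair_allowed",
    "SurrogateOracle",
    "TableOracle",
    "explore",
    "propagate_activity",
    "unique_reactions",
    "reaction_signature",
]


@dataclass
class Compound:
    """A network node: one molecular graph plus its canonical key."""

    graph: MolecularGraph
    key: str
    active: bool = False

    @classmethod
    def from_graph(cls, g: MolecularGraph, active: bool = False) -> "Compound":
        return cls(graph=g, key=canonical_key(g), active=active)


@dataclass
class ReactionRecord:
    """A recorded reaction between compounds of the network.

    Barriers and the reaction energy are kJ/mol; ``template`` is the label
    or index of the template that generated the trial, if any.
    """

    lhs: tuple[str, ...]  # compound keys, sorted
    rhs: tuple[str, ...]
    barrier_fwd: Optional[float] = None
    barrier_bwd: Optional[float] = None
    reaction_energy: Optional[float] = None
    template: Optional[str] = None
    mapped: Optional[MappedReaction] = None


@dataclass
class ExplorationConfig:
    """Exploration thresholds and limits.

    All energies in kJ/mol, masses in u.  Inequalities are strict: a
    barrier exactly at a threshold does not pass.
    """

    max_mass: Optional[float] = None
    barrier_active_max: float = 80.0
    energy_active_max: float = 50.0
    template_threshold: float = 90.0
    allow_same_sign_charges: bool = False
    max_generations: int = 10
    seed: int = 0
    excluded_reactions: frozenset = frozenset()  # signatures, see below

    def __post_init__(self):
        for name in ("barrier_active_max", "energy_active_max",
                     "template_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Network:
    """Compounds plus reaction records plus the per-generation log."""

    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: list[ReactionRecord] = field(default_factory=list)
    seeds: tuple[str, ...] = ()
    generations: list[dict] = field(default_factory=list)

    def active_keys(self) -> list[str]:
        return [k for k, c in self.compounds.items() if c.active]

    def to_jsonl(self) -> str:
        """Serialize to JSON lines: a manifest, then one record per line."""
        lines = [json.dumps({"kind": "manifest",
                             "seeds": list(self.seeds),
                             "n_compounds": len(self.compounds),
                             "n_reactions": len(self.reactions)},
                            sort_keys=True)]
        for key, c in self.compounds.items():
            lines.append(json.dumps(
                {"kind": "compound", "key": key, "active": c.active,
                 "elements": list(c.graph.elements),
                 "bonds": sorted([a, b] for a, b in c.graph.bonds),
                 "charge": c.graph.charge,
                 "stereo": [s or "" for s in c.graph.stereo],
                 "formal_charges": list(c.graph.formal_charges)},
                sort_keys=True))
        for r in self.reactions:
            rec = {"kind": "reaction", "lhs": list(r.lhs), "rhs": list(r.rhs),
                   "barrier_fwd": r.barrier_fwd, "barrier_bwd": r.barrier_bwd,
                   "reaction_energy": r.reaction_energy,
                   "template": r.template}
            if r.mapped is not None:
                rec["mapped"] = reaction_to_record(r.mapped)
            lines.append(json.dumps(rec, sort_keys=True))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "Network":
        from .molgraph import build_graph

        net = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            rec = json.loads(line)
            if rec["kind"] == "manifest":
                net.seeds = tuple(rec["seeds"])
            elif rec["kind"] == "compound":
                g = build_graph(rec["elements"], rec["bonds"],
                                charge=rec["charge"],
                                stereo=[s or None for s in rec["stereo"]],
                                formal_charges=rec["formal_charges"])
                net.compounds[rec["key"]] = Compound(
                    graph=g, key=rec["key"], active=rec["active"])
            elif rec["kind"] == "reaction":
                net.reactions.append(ReactionRecord(
                    lhs=tuple(rec["lhs"]), rhs=tuple(rec["rhs"]),
                    barrier_fwd=rec["barrier_fwd"],
                    barrier_bwd=rec["barrier_bwd"],
                    reaction_energy=rec["reaction_energy"],
                    template=rec["template"],
                    mapped=(reaction_from_record(rec["mapped"])
                            if "mapped" in rec else None)))
        return net


def charge_pair_allowed(c1: Compound, c2: Compound) -> bool:
    """Bimolecular charge filter: two molecules must not carry an overall
    charge of the same sign."""
    q1, q2 = c1.graph.charge, c2.graph.charge
    return not (q1 != 0 and q2 != 0 and (q1 > 0) == (q2 > 0))


def reaction_signature(lhs_keys: Iterable[str],
                       rhs_keys: Iterable[str]) -> str:
    """Direction-free signature of a reaction at the compound level."""
    sides = sorted((",".join(sorted(lhs_keys)), ",".join(sorted(rhs_keys))))
    return ">".join(sides)


# ---------------------------------------------------------------------------
# Step oracles


class SurrogateOracle:
    """Deterministic stand-in for an elementary-step search.

    Assigns each trial outcome a barrier and reaction energy by hashing the
    reaction's canonical compound-level signature together with the seed:
    barriers uniform on ``barrier_range`` kJ/mol, reaction energies uniform
    on ``energy_range``.  Purely a test scaffold — the numbers mean
    nothing chemically, but identical (trial, seed) always yield identical
    energies, and a reaction and its reverse are energetically consistent.
    """

    def __init__(self, seed: int = 0,
                 barrier_range: tuple[float, float] = (0.0, 200.0),
                 energy_range: tuple[float, float] = (-100.0, 100.0)):
        self.seed = seed
        self.barrier_range = barrier_range
        self.energy_range = energy_range

    def __call__(self, trial: Trial) -> list[tuple]:
        out = []
        for applied in apply_match(trial.match):
            lhs = [canonical_key(g) for g in trial.match.reactants]
            rhs = [canonical_key(g) for g in applied.products]
            sig = reaction_signature(lhs, rhs)
            h = hashlib.sha256(f"{sig}|{self.seed}".encode()).digest()
            u1 = int.from_bytes(h[:8], "big") / 2**64
            u2 = int.from_bytes(h[8:16], "big") / 2**64
            lo, hi = self.barrier_range
            barrier = lo + u1 * (hi - lo)
            lo, hi = self.energy_range
            energy = lo + u2 * (hi - lo)
            out.append((applied, barrier, energy))
        return out


class TableOracle:
    """Oracle that looks recorded energies up by template label.

    ``table`` maps a template label to ``(barrier_fwd, reaction_energy)``
    for the template's a->b direction; a trial matching side b is answered
    with the corresponding reverse energies.  Unknown trials are skipped,
    or handed to ``fallback`` if one is given.
    """

    def __init__(self, table: dict[str, tuple[float, float]],
                 fallback: Optional[Callable[[Trial], list]] = None):
        self.table = dict(table)
        self.fallback = fallback

    def __call__(self, trial: Trial) -> list[tuple]:
        label = trial.match.template.label
        if label not in self.table:
            return self.fallback(trial) if self.fallback else []
        barrier, energy = self.table[label]
        if trial.match.direction == "ba":
            barrier, energy = barrier - energy, -energy
        return [(applied, barrier, energy)
                for applied in apply_match(trial.match)]


# ---------------------------------------------------------------------------
# Exploration


def propagate_activity(net: Network, cfg: ExplorationConfig,
                       seeds: Optional[Sequence[str]] = None) -> set[str]:
    """Fixpoint of the activity rule, starting from the seed compounds.

    A reaction fires in a direction when *all* consumed-side compounds are
    active, its barrier in that direction is strictly below
    ``barrier_active_max`` and its reaction energy strictly below
    ``energy_active_max``; fired reactions activate all their products.
    Updates the compounds' ``active`` flags and returns the active key set.
    """
    seeds = tuple(seeds) if seeds is not None else net.seeds
    active = {k for k in seeds if k in net.compounds}
    changed = True
    while changed:
        changed = False
        for r in net.reactions:
            if reaction_signature(r.lhs, r.rhs) in cfg.excluded_reactions:
                continue
            for lhs, rhs, barrier, energy in (
                (r.lhs, r.rhs, r.barrier_fwd, r.reaction_energy),
                (r.rhs, r.lhs, r.barrier_bwd,
                 None if r.reaction_energy is None else -r.reaction_energy),
            ):
                if barrier is None or energy is None:
                    continue
                if not (barrier < cfg.barrier_active_max
                        and energy < cfg.energy_active_max):
                    continue
                if all(k in active for k in lhs) and not set(rhs) <= active:
                    active.update(rhs)
                    changed = True
    for key, c in net.compounds.items():
        c.active = key in active
    return active


def explore(start: Sequence[MolecularGraph], library: TemplateLibrary,
            oracle: Callable[[Trial], list], cfg: ExplorationConfig
            ) -> Network:
    """Run a template-filtered exploration from the start compounds.

    Per generation: enumerate unimolecular trials for every active compound
    and bimolecular trials for every unordered active pair (self-pairs
    included) passing the charge filter; filter them through the template
    library at ``cfg.template_threshold``; evaluate survivors with the
    oracle; register products with mass at most ``cfg.max_mass``; then
    re-propagate activity.  Stops when a generation adds nothing or after
    ``cfg.max_generations``.
    """
    if not start:
        raise ValueError("exploration needs at least one start compound")
    net = Network()
    for g in start:
        c = Compound.from_graph(g, active=True)
        net.compounds.setdefault(c.key, c)
    net.seeds = tuple(net.compounds)
    processed: set[str] = set()
    recorded: set[tuple] = set()

    for gen in range(cfg.max_generations):
        new_compounds = 0
        new_reactions = 0
        active = [net.compounds[k] for k in net.compounds
                  if net.compounds[k].active]
        reactant_sets: list[tuple[Compound, ...]] = [(c,) for c in active]
        for i, c1 in enumerate(active):
            for c2 in active[i:]:
                if cfg.allow_same_sign_charges or charge_pair_allowed(c1, c2):
                    reactant_sets.append((c1, c2))
        for rset in reactant_sets:
            graphs = tuple(c.graph for c in rset)
            for trial in enumerate_trials(library, graphs,
                                          cfg.template_threshold):
                tsig = (tuple(sorted(c.key for c in rset)),
                        trial.match.template.label,
                        trial.match.certificate)
                key = repr(tsig)
                if key in processed:
                    continue
                processed.add(key)
                for applied, barrier, energy in oracle(trial):
                    if cfg.max_mass is not None and any(
                            p.mass > cfg.max_mass for p in applied.products):
                        continue
                    rhs_keys = tuple(sorted(
                        canonical_key(p) for p in applied.products))
                    lhs_keys = tuple(sorted(c.key for c in rset))
                    sig = reaction_signature(lhs_keys, rhs_keys)
                    if sig in cfg.excluded_reactions:
                        continue
                    for p in applied.products:
                        pk = canonical_key(p)
                        if pk not in net.compounds:
                            net.compounds[pk] = Compound(graph=p, key=pk)
                            new_compounds += 1
                    rec_id = (lhs_keys, rhs_keys,
                              trial.match.template.label, barrier)
                    if rec_id in recorded:
                        continue
                    recorded.add(rec_id)
                    mapped = applied.reaction
                    mapped = MappedReaction(
                        lhs=mapped.lhs, rhs=mapped.rhs,
                        atom_map=mapped.atom_map, barrier_fwd=barrier,
                        barrier_bwd=barrier - energy,
                        reaction_energy=energy)
                    net.reactions.append(ReactionRecord(
                        lhs=lhs_keys, rhs=rhs_keys, barrier_fwd=barrier,
                        barrier_bwd=barrier - energy, reaction_energy=energy,
                        template=trial.match.template.label, mapped=mapped))
                    new_reactions += 1
        propagate_activity(net, cfg)
        net.generations.append({"generation": gen,
                                "new_compounds": new_compounds,
                                "new_reactions": new_reactions})
        if new_compounds == 0 and new_reactions == 0:
            break
    return net


def unique_reactions(net: Network) -> tuple[int, dict[str, list[ReactionRecord]]]:
    """Group reactions by unordered compound-level sides.

    A reaction and its reverse count as one; returns the group count and
    the groups keyed by signature.
    """
    groups: dict[str, list[ReactionRecord]] = {}
    for r in net.reactions:
        groups.setdefault(reaction_signature(r.lhs, r.rhs), []).append(r)
    return len(groups), groups
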