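"""Template-filtered exploration of the ethylene-oxide polymerization.

A single chain-elongation template with a recorded 72 kJ/mol barrier is
applied to an exploration capped at the mass of the n=3 oligomer.  The
network converges to the two start compounds plus one compound per chain
length, all active under the strict 80/50 kJ/mol thresholds — the
template filter admits no side chemistry.
"""

from rxntemplates import fixtures as fx
from rxntemplates.explorer import (
    ExplorationConfig,
    TableOracle,
    explore,
    unique_reactions,
)
from rxntemplates.templates import TemplateLibrary

peo = fx.peo_system()
n3_mass = peo.reaction.rhs[0].mass + 2 * fx.ethylene_oxide().mass
cfg = ExplorationConfig(max_mass=n3_mass + 0.1, seed=1)
net = explore(peo.start, TemplateLibrary([peo.template]),
              TableOracle(peo.oracle_table), cfg)

print(f"compounds: {len(net.compounds)} "
      f"(active: {len(net.active_keys())})")
print(f"reactions: {len(net.reactions)} "
      f"({unique_reactions(net)[0]} unique)")
for rec in net.reactions:
    print(f"  {' + '.join(k.split(':')[0] for k in rec.lhs)} -> "
          f"{' + '.join(k.split(':')[0] for k in rec.rhs)}   "
          f"barrier {rec.barrier_fwd:.0f} kJ/mol, "
          f"energy {rec.reaction_energy:+.0f} kJ/mol")
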