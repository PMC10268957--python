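# rxntemplates

Reaction templates on molecular graphs: extraction from atom-mapped
reactions, deduplication by template-graph isomorphism, and application as
filters that generate product graphs and steer autonomous reaction-network
explorations.

## The problem

First-principles exploration of chemical reaction networks suffers a
combinatorial catastrophe: every compound can in principle react with every
other, and most attempted elementary-step searches fail or lead nowhere of
interest.  `rxntemplates` encodes knowledge about *reactions already seen*
in a minimal, transferable form and uses it to decide which reaction trials
are worth attempting, for people building or analyzing exploration
campaigns (and for anyone who wants graph-level reaction rules without
SMARTS or bond orders).

## The template abstraction

Molecules are graphs with **binary bonds** (an edge exists or it does not)
whose atoms carry the element, a local coordination shape (terminal, bent,
trigonal planar, tetrahedron, ... — a degree-based proxy for
hybridization) and an optional stereo descriptor.  Given a reaction with an
exact atom map, the template keeps

* exactly the atoms whose bonding pattern changes,
* their grouping into *fragments* (connected components of the
  reactive-atom subgraph) and into the *molecules* those fragments came
  from,
* a list of allowed shapes per atom (merging duplicates unions the lists),
* the formed/broken bonds and any recorded barriers Δ‡ (kJ/mol).

Template identity is exact isomorphism of a combined labeled graph (atom,
fragment and molecule nodes; containment, cross-side mapping, and bond
edges, with bonds that do not survive to the other side labeled as
changed), with the two sides allowed to swap.  A template *matches* a set
of reactants when all fragments of one side embed without overlapping
atoms — fragments of one template molecule into a single reactant,
distinct template molecules into distinct reactants — and applying the
encoded bond edits to the reactant union graph yields the product graphs.

The explorer (`rxntemplates.explorer`) grows a network generation by
generation: unimolecular trials for every active compound, bimolecular
trials for every pair that does not carry same-sign charges, template
filtering by the lowest recorded barrier (strictly below a 90 kJ/mol
threshold by default), a pluggable step oracle in place of the
electronic-structure layer, a product mass cap, and activity propagation
(compounds reachable from the seeds through reactions with Δ‡ < 80 kJ/mol
and ΔG < 50 kJ/mol, strictly).

## Worked example

```python
from rxntemplates import fixtures as fx
from rxntemplates.explorer import ExplorationConfig, TableOracle, explore
from rxntemplates.templates import TemplateLibrary

peo = fx.peo_system()          # ethoxide + ethylene oxide, one template
n3 = peo.reaction.rhs[0].mass + 2 * fx.ethylene_oxide().mass
net = explore(peo.start, TemplateLibrary([peo.template]),
              TableOracle(peo.oracle_table),
              ExplorationConfig(max_mass=n3 + 0.1, seed=1))
print(len(net.compounds), len(net.active_keys()), len(net.reactions))
```

prints `5 5 3`: the two start compounds plus one compound per chain length
up to the mass cap (n = 1..3), all active, grown by three recorded
elongation reactions — a single template reproduces the whole anionic
polymerization and admits nothing else.  The scripts in `examples/` walk
through extraction/deduplication (`01`), product generation (`02`), this
exploration (`03`), the stereo-aware propylene-oxide enumeration that
yields `3^5 = 243` distinct pentamers (`04`), and template-based network
analysis — occurrence spectra and pairwise graph edit distances — on an
imported snapshot (`05`).

A thin CLI wraps the same functions:

```bash
rxntemplates fixtures peo_elongation -o reaction.json
rxntemplates extract reactions.jsonl -o library.json
rxntemplates explore config.json -o network.jsonl
rxntemplates import-scine snapshot.json -o library.json
```

## Layout

| module | contents |
| --- | --- |
| `molgraph` | graphs, shapes, isomorphism, embeddings, canonical keys |
| `reactions` | atom-mapped reactions, validation, bond-change detection |
| `templates` | extraction, template graphs, dedup/merge, GED, spectra |
| `matching` | template matching, product generation, trial filtering |
| `explorer` | network model, oracles, exploration loop, activity closure |
| `scine_adapter` | offline import of exported network snapshots |
| `fileio` | XYZ + bond-list reader |
| `fixtures` | worked examples and random-instance generators |

`docs/methods.md` documents the model, its parameters and its limits.
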