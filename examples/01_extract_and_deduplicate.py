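"""Extract reaction templates from atom-mapped reactions and deduplicate.

A template keeps only the atoms whose bonding pattern changes, grouped
into fragments and molecules, with the local shape of each atom.  Two
chain-elongation steps of different chain length produce the *same*
template, so deduplication collapses them into one entry with an
occurrence count of 2.
"""

from rxntemplates import fixtures as fx
from rxntemplates.matching import apply_match, match_template
from rxntemplates.templates import deduplicate, extract_template

da = extract_template(fx.diels_alder(), label="diels_alder")
print("Diels-Alder template:")
print(f"  reactant side: {da.side_a.n_atoms} atoms in "
      f"{da.side_a.n_fragments} fragments across "
      f"{da.side_a.n_molecules} molecules")
print(f"  product side:  {da.side_b.n_atoms} atoms in "
      f"{da.side_b.n_fragments} fragment")
print(f"  bonds formed: {len(da.formed)}, broken: {len(da.broken)}")

# the elongation template extracted at n=0->1 and at n=1->2
peo = fx.peo_system()
(m,) = match_template(peo.template, (peo.reaction.rhs[0],
                                     fx.ethylene_oxide()))
(second_step,) = apply_match(m)
lib = deduplicate([extract_template(peo.reaction),
                   extract_template(second_step.reaction)])
print(f"\n2 elongation steps -> {len(lib)} template "
      f"(occurrence count {lib[0].occurrence_count})")
print("recorded forward barriers (kJ/mol):", lib[0].barriers_ab)
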