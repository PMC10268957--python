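"""Stereo-aware enumeration of propylene-oxide oligomers.

Each chain-growth step offers an attack at the unsubstituted ring carbon
(no new stereocenter) or at the methyl-bearing carbon, which becomes a
center with four distinct branches and is emitted once per descriptor —
three outcomes per addition, hence 3**n distinct n-mers.
"""

from rxntemplates import fixtures as fx
from rxntemplates.matching import apply_match, match_template
from rxntemplates.molgraph import canonical_key

ppo = fx.ppo_system()
generation = {canonical_key(ppo.start[0]): ppo.start[0]}
for step in range(1, 6):
    nxt = {}
    for chain in generation.values():
        for m in match_template(ppo.template, (chain, ppo.monomer)):
            if m.side != "a":
                continue
            for applied in apply_match(m):
                (product,) = applied.products
                nxt[canonical_key(product)] = product
    generation = nxt
    print(f"n={step}: {len(generation)} distinct chains (3^{step} = "
          f"{3 ** step})")
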