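"""Apply a template to reactants and generate the product graphs.

The chain-elongation template places its alkoxide-O fragment on the
ethoxide and its C-O fragment on the epoxide ring; applying the encoded
bond changes opens the ring into the n=1 chain alkoxide.  The attack at
either ring carbon is symmetry-equivalent, so exactly one match survives.
"""

from rxntemplates import fixtures as fx
from rxntemplates.matching import apply_match, match_template
from rxntemplates.molgraph import canonical_key, molecular_formula

peo = fx.peo_system()
matches = match_template(peo.template, peo.start)
print(f"matches on (ethoxide, ethylene oxide): {len(matches)}")

(applied,) = apply_match(matches[0])
for p in applied.products:
    print(f"product: {molecular_formula(p)} charge {p.charge:+d} "
          f"key {canonical_key(p)}")
formed, broken = matches[0].host_edits()
print(f"bond changes applied: formed {sorted(formed)}, "
      f"broken {sorted(broken)}")
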