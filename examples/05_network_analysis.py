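"""Analyze an imported network snapshot with templates.

The packaged synthetic snapshot (shaped like an exported exploration
database) is imported, its reactions are folded into templates, and the
network is summarized as an occurrence spectrum — one entry per template,
positioned by its lowest recorded barrier — plus the pairwise template
graph-edit-distance matrix.
"""

import importlib.resources
import warnings

from rxntemplates.scine_adapter import load_network
from rxntemplates.templates import (
    barrier_spectrum,
    deduplicate,
    extract_template,
    ged_matrix,
)

path = importlib.resources.files("rxntemplates") / "data" \
    / "scine_mini_synthetic.json"
imported = load_network(str(path))
print(f"imported {len(imported.reactions)} reactions "
      f"({imported.n_skipped} skipped: "
      f"{[sid for sid, _ in imported.skipped]})")

lib = deduplicate(extract_template(r) for r in imported.reactions)
print(f"{len(lib)} deduplicated templates")

spectrum = barrier_spectrum(lib, imported.reactions)
print("\noccurrence spectrum (sorted by lowest recorded barrier):")
for e in spectrum.entries:
    print(f"  template {e.index}: {e.count} reactions, "
          f"min barrier {e.min_barrier:.0f} kJ/mol, "
          f"all barriers {[round(b) for b in e.barriers]}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    mat, order = ged_matrix(lib)
print("\npairwise template GED matrix (barrier-ordered):")
print(mat)
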