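# Methods

## Molecular graph model

A molecule is an undirected graph of atoms and **binary bonds**.  Bond
orders are deliberately not stored: an input bond order contributes an
edge when it is ≥ 0.5 and is then forgotten.  This keeps all downstream
analyses on the existence of edges rather than their weights, at the cost
of conflating e.g. a carbonyl C=O with an alkoxide C–O (both are single
edges); the shape labels recover part of that information.

Each atom carries

* the element symbol (validated against a standard-atomic-weight table,
  IUPAC 2021 abridged values, which also supplies molecular masses in u),
* a **local coordination shape**, assigned deterministically from the
  bonded-neighbor count: 0 → isolated, 1 → terminal, 2 → bent (or linear
  when the caller flags the atom as unsaturated), 3 → trigonal planar,
  4 → tetrahedron, k > 4 → `other(k)`.  This degree-based taxonomy is an
  explicit stand-in for a geometric shape classifier operating on 3D
  structures; it reproduces the dangling-bond pictures that make templates
  readable without any geometry, but it cannot distinguish, say, T-shaped
  from trigonal-planar three-coordination,
* an optional **stereo descriptor** in {none, A, B}: a minimal two-valued
  label for a center whose four branches are pairwise distinct (branch
  distinctness is judged by canonical certificates of the branch subgraphs
  rooted at each neighbor).  Descriptors are assigned only when template
  application edits an atom into such a center — one product variant per
  descriptor value — and are respected by isomorphism and compound
  identity.  The model distinguishes the two arrangements without
  assigning R/S labels and does not cover double-bond geometry or axial
  chirality.

Per-atom **formal charges** (summing to the total charge) are bookkeeping
used to split the total charge over product molecules; they are not part
of compound identity.  When absent on charged input, the total charge is
placed on the most valence-deficient atom, which resolves correctly for
the anionic species handled here (alkoxides, halides, hydride).

## Canonical compound keys

Compound identity needs `key(g1) == key(g2)` exactly when the graphs are
isomorphic (elements, stereo, total charge).  Keys are computed by an
individualization–refinement canonical labeling: degree-1 leaves are first
folded into their neighbor's label (removing the branching that symmetric
terminal hydrogens would cause), colors are refined by neighbor-color
multisets, and remaining non-singleton cells are resolved by branching
over all individualizations, keeping the lexicographically minimal
serialization.  This is worst-case exponential but refines almost
completely on molecular graphs; the suite validates key equality against
brute-force permutation search and VF2 on random graphs.  Isomorphism
queries themselves use VF2 (networkx), so key computation and isomorphism
are two independent routes.

## Templates

Extraction keeps exactly the atoms incident to a formed or broken bond
(the symmetric difference of the mapped edge sets), their induced bonds,
their fragment/molecule grouping, the observed shape per atom (as a
singleton allowed-shape list), the per-atom formal charges of both sides,
and the reaction's recorded barriers.  Spectator molecules are dropped.
Identity is isomorphism of the combined template graph — atom, fragment
and molecule nodes; containment edges; the cross-side atom mapping; bond
edges labeled *changed* when the bond does not exist on the other side —
under all labels, with the side roles allowed to swap.  A single "changed"
edge kind (rather than separate formed/broken kinds) is what makes a
template equal to its own reverse reading; the direction-specific
formed/broken classification is recovered from side membership whenever
needed (e.g. DOT export).

Fragment and molecule nodes are retained although their information is
derivable: they make the graphs readable and let non-matching comparisons
terminate early.

**Deduplication** merges shape-agnostically isomorphic templates: shape
lists are united atom-wise along the isomorphism, barrier lists are
concatenated respecting the matched orientation, occurrence counts are
summed.  Strict identity (shape lists equal as sets) is only meaningful
after this merge closure — during deduplication shape-agnostic matching
must trigger the merge, otherwise shape lists could never grow.  On merge
the first template's formal charges are kept; merging reactions whose
reactive atoms disagree in formal charge is not expected in practice and
would only affect product charge splitting, not template identity.

**Graph edit distance** between template graphs uses unit costs for node
and edge insertion, deletion and relabeling.  Strictly identical templates
short-circuit to an exact 0 via the isomorphism test.  Otherwise an exact
A\*-style edit-path search (networkx) runs when the two graphs together
have at most 24 nodes — beyond that the exact search becomes intractable
because fragment and molecule nodes are mutually indistinguishable — and
larger pairs get a symmetric assignment-style upper bound, flagged with
`ApproximateGEDWarning`.  The GED matrix of a library is ordered by each
template's minimal recorded barrier, unknown barriers last.

## Matching and application

A template side applies to a reactant set when its molecule count equals
the reactant count and every fragment embeds injectively — elements equal,
host shape within the allowed list, fragment bonds preserved — with
fragments of one template molecule placed atom-disjointly in a single
reactant and distinct template molecules in distinct reactants.
Embeddings are **monomorphisms**: extra host bonds between matched atoms
are permitted, which is also why an application can be rejected at edit
time (adding a bond that already exists) — such matches are reported as
rejected with a diagnostic rather than silently dropped.  Both template
sides are tried, so every template is usable in both directions; a
unimolecular side may match a substructure of an arbitrarily large
molecule, which is exactly what lets one elongation template drive a
polymerization at every chain length.

All distinct placements are reported.  Two placements are considered the
same trial when the reactants-plus-role-assignment graphs are isomorphic
(equal canonical certificates); this collapses duplicates arising from
template automorphisms *and* host symmetry — e.g. the attack at either
carbon of ethylene oxide is one trial, while the two inequivalent carbons
of propylene oxide remain two.

Application translates the template's bond edits through the match,
rewrites the union graph, transfers the opposite side's formal charges to
the matched atoms (this is how the negative charge moves from nucleophile
to leaving group), re-evaluates stereo descriptors at every edited atom,
splits the result into connected components and emits the products with
an identity-outside-the-template atom map.  Element multiset and total
charge conservation are asserted property-style across the suite.

## Exploration

The explorer is a surrogate for a full exploration stack: it reproduces
the filtering logic while the elementary-step search plus electronic
structure is replaced by a pluggable **step oracle**.

Parameters (`ExplorationConfig`, energies kJ/mol, masses u):

| parameter | default | meaning |
| --- | --- | --- |
| `template_threshold` | 90 | a matched direction's lowest recorded barrier must be strictly below this for a trial to be generated |
| `barrier_active_max` | 80 | activity propagation: Δ‡ must be strictly below |
| `energy_active_max` | 50 | activity propagation: ΔG must be strictly below |
| `max_mass` | none | products above the cap are discarded at registration, their reactions not recorded |
| `allow_same_sign_charges` | false | bimolecular pairs with same-sign net charges are skipped |
| `max_generations` | 10 | hard stop for the generational loop |

All threshold comparisons are strict, reading "lower than" literally; a
reaction sitting exactly at 80 kJ/mol does not activate its products.
Activity propagation fires a reaction direction only when *all*
consumed-side compounds are active (the closure thus matches what the
explorer itself would trial); it is validated against an independent
worklist implementation on random networks.  An exclusion list of
compound-level reaction signatures supports retrospectively removing a
reaction from the kinetic analysis without deleting its record.

Two oracles ship: a **table oracle** returning recorded energies per
template label (reverse-direction trials get the barrier/energy implied by
Δ‡ − ΔG), and a **surrogate oracle** hashing the reaction's canonical
signature together with a seed into uniform energies (Δ‡ ∈ [0, 200],
ΔG ∈ [−100, 100] kJ/mol) — a deterministic test scaffold with no chemical
content.  Given identical inputs and seed the whole loop is deterministic
to the serialized byte.

## Fixtures and what they do (not) show

The fixture module generates every worked example programmatically:
Diels–Alder, SN2, the anionic ethylene-/propylene-oxide polymerizations,
a hydride abstraction, and seeded random reactions (random connected
graph + planted edit + random relabeling).  Fixture energies are chosen,
not computed: the elongation carries a 72 kJ/mol forward barrier and a
−30 kJ/mol reaction energy (hence a 102 kJ/mol reverse barrier, above the
90 kJ/mol application threshold, so depolymerization is filtered out);
the hydride abstraction is nearly barrierless at −200 kJ/mol.  Passing
tests therefore demonstrate the graph/filter logic, not energetics: real
explorations face noisy barriers, failed step searches, conformers and
side chemistry that the table oracle does not emulate.  The packaged
`scine_mini_synthetic.json` is likewise a constructed stand-in shaped like
an exported exploration database (structures with bond-order lists,
elementary steps with Hartree energies at 1 Hartree = 2625.499639 kJ/mol,
including one defective record to exercise skip reporting); it is not
derived from any deposited data set.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
oligomer enumerations to n = 5 (3^5 = 243 chains of ~60 atoms),
explorations capped at the n = 3 oligomer mass, random-instance property
checks at ≤ 10 atoms / ≤ 50 compounds, and GED matrices over a handful of
templates.  These sizes keep every check in seconds while exercising the
same code paths a production-size network would.

## Known limitations

* Shapes are degree-based, so templates cannot separate reactions that
  differ only in true 3D coordination geometry.
* The stereo model handles tetrahedral centers created by an edit; it does
  not track double-bond geometry, ring stereochemistry or existing centers
  whose environment changes without a bond edit.
* Atom maps are required input; no mapping inference is attempted.
* Formal-charge transfer assumes the template's source reaction is
  representative of every application site.
* Multi-step elementary processes are treated as single end-to-end
  reactions; intermediates are invisible to extraction.
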