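# Methods

## Model

`cationet` treats a carbocation as a connected molecular graph over C and H
atoms with integer bond orders 1 and 2 and at most one designated cationic
carbon.  The cationic carbon is classical: trivalent, all-single-bonded,
never part of a C=C (vinyl-type and non-classical bridged cations are
outside the model).  Hydrogens are explicit graph atoms, because two of the
five operators (hydride shift, proton transfer) move individual hydrogens
and the eligibility rule below refers to them directly.

Species identity is constitutional: two graphs are the same species iff
their canonical SMILES (computed with RDKit over the heavy-atom graph with
hydrogen counts folded in) coincide.  Stereodescriptors are erased before
canonicalization, so configurational isomers — including the cis/trans
forms of the linear substrate cation — collapse onto one node.  Skeleton-
and route-level results are stereo-independent, which is what this package
is for; a `use_stereo` flag exists for callers that carry stereo tags.

### Reaction operators

Every atom of a reactant is eligible for rearrangement except the cationic
carbon and its three bonded atoms (those four atoms are the ionization /
resonance frame).  For each eligible atom, each enabled operator whose
structural precondition matches is applied:

- **Alkylation** bonds the cationic carbon to an eligible alkene carbon,
  demotes the double bond, and moves the charge to the other alkene
  carbon.  Alkenes conjugated with the charge (either carbon adjacent to
  it) are excluded — that interaction is allylic resonance, not
  cyclization.  The smallest ring formed is a cyclopropane (required for
  thujane/carane-type skeletons).
- **Alkyl and methyl shifts** are 1,2-migrations: a carbon bonded to an
  anchor carbon adjacent to the charge site migrates onto the cationic
  carbon, the charge moving to the anchor.  Methyl migrations are a
  separate operator type (so they can be toggled independently); the
  anchor must be sp3, since the charge would otherwise land on an alkene
  carbon.  Migrating a ring bond performs ring expansion or contraction.
- **Hydride shifts** move an eligible H to the cationic carbon, the charge
  moving to the H's origin carbon.
- **Proton transfer** is one concerted edit: an H β to the charge site
  leaves (its carbon forms a C=C with the old cationic carbon) and
  protonates a carbon of a remote alkene, the charge appearing on that
  alkene's other carbon.  The donor carbon must be sp3 — deprotonating an
  sp2 donor would create a cumulated diene, which we exclude as
  chemically unreasonable for this family.
- **Resonance** edges connect allylic partners (charge moved across an
  adjacent C=C, applied to closure for conjugated polyenes).  They are
  bookkeeping, not chemistry: zero-cost in routes and folded into a
  node's own discovery round.

Operators conserve the formula and, in (rings, double bonds) terms, change
it by (+1, −1) for alkylation and (0, 0) for everything else.  A
consequence worth stating: cyclization is one-way within this operator
family — no operator carries the inverse (−1, +1) delta, so ring opening
back to an alkene never occurs.  The enumeration is a forward closure
from the substrate, which is the quantity of interest; shift and
proton-transfer steps are individually reversible (verified exhaustively
on the C5 spaces).

Products that violate a graph invariant (e.g. a shift that would place the
charge on an sp2 carbon) are dropped with a debug-log entry; degenerate
products equal to the reactant are emitted by the operators and removed at
network insertion, keeping each operator pure and locally testable.

### Closure engine

Enumeration is breadth-first: round *r* applies all enabled operators to
every node discovered in round *r − 1*, deduplicates by canonical key,
applies the stability filter, and records one directed edge per generating
event (identity = reactant, product, type, participating atoms).  Rejected
keys are memoized so the filter runs once per species.  The run stops at a
fixpoint or a round cap.  Node and edge sets are independent of seed atom
numbering and iteration order because identity is canonical.

### Stability filtering

Three modes: *permissive* (accept all — used for exhaustive constitutional
mapping and the alkane validation, where energies play no role),
*heuristic* (reject configured substitution classes, default primary, with
allylic cations always exempt — the linear substrate itself is formally an
allylic primary cation and must survive), and *energy_plugin* (accept iff
energy minus the reference cation's energy is ≤ a cutoff, boundary
inclusive so the reference passes at 0.0 kcal/mol).  The energy engine is
a contract — deterministic `evaluate(graph) -> kcal/mol` — not an
implementation; semi-empirical engines sit behind it via the bundled
JSON-over-subprocess adapter, and a table-lookup stub serves tests.  The
filter is monotone: a stricter cutoff can only remove species, so networks
under nested cutoffs nest.

### Skeletons and routes

A skeleton is obtained by neutralizing the cation with a hydride quench at
the charge site, dropping hydrogens, and deleting saturated degree-1
carbons to fixpoint.  The hydride quench is deliberate: it is the unique
neutralization that leaves the substrate's alkene pattern untouched
(deprotonation would move double bonds and change skeleton identities).
Exocyclic alkene carbons survive pruning (they are unsaturated).  For the
C10H17+ network, rings + double bonds is pinned at 2, so cyclic skeletons
are either one ring plus one double bond or one of the four two-ring
topologies.  Topology is read off the subgraph of ring bonds: two
components = separated rings; a ring-degree-4 atom = spiro; two branch
atoms adjacent = fused (one shared bond); non-adjacent = bridged.  More
than two rings raises, as it would violate the unsaturation bound.

Route lengths use the substrate chemistry's step convention: step 1 is
creation of the trans linear cation, step 2 the trans/cis isomerization —
neither resolved by the constitutional network — so a node's step count is
its chemical hop count from the seed plus 2, and the first cyclization
products sit at step 3.  Shortest routes are computed by a deterministic
Dijkstra with resonance edges at cost 0 and lexicographic tie-breaking;
per-skeleton `min_step` is the minimum over member cations.  With
identical configuration, step count equals discovery round + 2 (checked as
an internal consistency test).

The five monoterpene skeletons with assigned EC numbers — the
menthane-type cyclohexene and the pinane, bornane, thujane and carane ring
frames — ship as a configurable list of canonical framework keys used by
the recovery and step-4 reports; the list is configuration, not code.

## Parameters and defaults

| parameter | default | meaning |
| --- | --- | --- |
| `enabled_types` | all six | operator toggle set |
| `max_rounds` | 10 | round cap (None = fixpoint) |
| `shift_range_bonds` | 4 | through-bond cap on hydride shift / proton transfer (None = unlimited) |
| `stability.mode` | permissive | filter mode |
| `stability.cutoff_kcal` | 0.0 | energy excess over the reference (plugin mode) |
| `dihedral_window_deg` | 45 | stereo-duplication trigger window (inclusive) |
| `distance_cutoff_A` | 5.0 | geometric donor–acceptor gate (inclusive) |
| `gate_after_round` | 5 | first round after which the geometric gate applies |
| `conformer_rounds` | 5 | rounds with conformer sampling (geometric mode) |

`shift_range_bonds` is the topological stand-in for the geometric
donor–acceptor distance gate: it keeps default runs deterministic and
3D-free while still expressing that long-range hydride shifts and proton
transfers are permitted early and restricted late.  The exhaustive study
run lifts it entirely (`None`), which makes the enumeration a
constitutional superset of any geometrically gated run.

The study conditions used by the acceptance machinery are: the linear
C10H17+ allylic cation as seed (resonance partners auto-added at round 0),
all operators, permissive filter, unlimited shift range, 10 rounds.  Under
these conditions the network saturates (36 new species in round 10 of
34445 total), so the 10-round cap loses essentially nothing while bounding
the runtime to a few minutes on one CPU.

## Geometric mode

Geometric mode is off by default and none of the headline results use it;
it exists so that coordinate-dependent engines can be plugged in without
changing the topological core.  Its pieces are contracts with small
deterministic reference implementations: an RDKit ETKDG embedder, a UFF
minimizer plus a bonded-terms harmonic relaxer, a rigid torsion-scan
conformer generator, the ±45° (inclusive) stereo-duplication rule built
from the sp2 plane normals of the cationic carbon, and the 5.0 Å
(inclusive) donor–acceptor gate active after round 5.  Any returned
geometry must keep bonded pairs within 0.9–1.8 Å.  Boundary inclusivity at
±45° and 5.0 Å is a package decision; the rules' sources state the values
but not the boundary behavior.

## What the validation does and does not show

The alkane validation (shift operators only, linear CnH(2n+1)+ seeds,
n = 4…8 by default) checks the engine against an independently constructed
ground truth: every constitutional alkyl-cation isomer, built as carbon
trees crossed with H-bearing charge placements.  Set equality of canonical
keys — not just equal counts — is required.  This exercises shifts,
deduplication and closure, but not alkylation or proton transfer (alkanes
have no alkenes); those operators are covered by hand-derived textbook
rearrangements (homoallyl ↔ cyclopropylcarbinyl/cyclobutyl, neopentyl →
tert-amyl, pinacol-type shifts, the 1,6-/1,7-ring closures of the linear
substrate) and by the conservation/accounting property tests over the full
monoterpene network.

The enumerated constitutional space is deliberately a superset of what an
energy- and geometry-filtered study reports: it contains species a
semi-empirical filter would reject (48%+ of nodes are secondary cations
under permissive settings) and skeletons reachable only through them.
Counts derived from it therefore upper-bound geometry-filtered counts.
In particular the number of skeletons first reachable at step 4 is larger
here than in geometrically gated studies, for two structural reasons: the
linalyl-type resonance seed opens 1,4-/1,5-ring closures at step 3, and
unlimited-range proton transfers generate exocyclic-alkene skeletons one
step after each cyclization.  Conversely, only two of the EC-referenced
frames (pinane, bornane) are reachable one operator beyond the first
cyclization: thujane- and carane-type frames need a cyclopropane closure
whose homoallylic charge arrangement first exists a step later, so they
appear at step 5.

## Known limitations

- Constitutional mode cannot distinguish stereoisomeric intermediates, so
  member counts per skeleton are lower than in stereo-resolved studies and
  the two stereoisomeric 1,6-cyclization intermediates appear as one node.
- No termination chemistry: the network contains cations only, not the
  quenched (deprotonated/hydrated) products.
- No energy engine is bundled; heuristic filtering by substitution class
  is a coarse stand-in, and reproducing published energy-filtered counts
  requires plugging in the corresponding engine.
- Cyclization is irreversible within the operator set (see above), so the
  network is a DAG-like forward closure rather than a fully reversible
  reaction graph.
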