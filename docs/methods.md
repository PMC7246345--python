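# Methods

`enznet` compares two orthogonal classifications of enzyme function in
functionally diverse superfamilies: the *evolutionary* view (a strict
superfamily > subgroup > family hierarchy inferred from sequence and
structure, with monofunctional families) and the *chemical* view (what the
overall reaction actually does to bonds and molecules).  The toolkit links
the two through the enzyme functional domain (EFD) — the smallest
contiguous sequence span responsible for exactly one overall reaction —
and quantifies their agreement on thresholded similarity networks.

## Molecules and fingerprints

Molecules are heavy-atom graphs parsed and written through RDKit (SMILES
and MDL MOL V2000).  Hydrogens are implicit: per-atom total-H counts are
kept as atom attributes, which keeps the atom-mapping search tractable and
follows standard cheminformatics practice.  Aromaticity is perceived on
input, so kekulized and aromatic notations normalize to the same canonical
graph; canonical form is the RDKit canonical SMILES, and canonicalization
is idempotent.  Stereochemistry is carried as CIP flags (R/S on atoms, E/Z
on bonds); "either"/unknown marks are normalized to no-stereo.  Charge and
protonation states are compared as given, with no pH normalization.

The circular fingerprint of a molecule is the multiset of hashed
environment features: for every seed atom and every radius r in 0..R, one
feature encoding the labeled subgraph within graph distance r of the seed.
Environment identity is computed by Weisfeiler–Lehman refinement seeded
with (element, formal charge, H count, stereo flag, distance-from-seed
layer) and refined over bond orders; the signature is hashed with blake2b,
so fingerprints are identical across runs, platforms and atom input
orders.  There are no random seeds anywhere in the fingerprint.  The
default radius is 2, the conventional circular-fingerprint depth; the
feature count is dynamic (it grows with molecule size and radius).
Tanimoto similarity is intersection-over-union; the default is *multiset*
semantics (duplicate environments counted) because the small acid-sugar
scaffolds typical of these superfamilies contain many repeated
environments and set semantics saturates; set semantics is available via a
flag.  Two empty fingerprints score 0.0 by convention.

The test suite verifies the fingerprint against an independent oracle:
explicit BFS enumeration of every environment plus brute-force labeled
graph isomorphism, asserting that feature-hash equality coincides exactly
with rooted-environment isomorphism on all corpus molecules with <= 8
heavy atoms.

## Reactions

A reaction is substrate and product molecule lists plus a directionality
tag (reversible is the curation default; unknown renders as `?`), a
cognate/generic type (generic marks wildcard R-group components), an
optional EC number and opaque external references.  I/O covers reaction
SMILES and MDL RXN V2000.  The per-element atom balance (H included) is a
report, not an exception: curated cognate reactions should balance, while
generic reactions may not.  Atom mapping, however, refuses reactions that
are not heavy-atom balanced.

An overall reaction is recorded once regardless of how many schemes
(mechanisms) exhibit it.  The canonical reaction key is the sorted
canonical SMILES of each side joined by `>>`; reversible and
unknown-direction reactions are additionally normalized to the
lexicographically smaller orientation, giving deterministic deduplication.

## Atom–atom mapping

The mapping is an element-respecting bijection between substrate and
product heavy atoms minimizing the number of implied bond changes (the
minimum-chemical-distance principle).  Wildcard atoms match any element.
The search is depth-first iterative deepening over cost targets with two
admissible lower bounds:

* a per-position bound — when atom *i* is assigned to candidate *p*, every
  substrate bond from *i* to an earlier-assigned atom is either preserved
  (requiring a same-(order, element) incident bond at *p*) or costs at
  least one change;
* a global bond-multiset bound — every not-yet-settled substrate bond must
  be preserved by a not-yet-settled product bond with the same (order,
  element pair) or cost a change, and symmetrically, so the larger
  multiset deficit bounds the remaining cost.

At the first feasible cost target, the first solution found by the
lexicographic DFS (substrate atoms and candidates iterated in canonical
atom-rank order) is the lexicographically smallest minimum-cost mapping,
which makes results deterministic and independent of input atom order.  A
node-expansion budget (default 500 000) turns pathological searches into
an explicit error rather than a silently suboptimal answer.  The largest
worked example (the o-succinylbenzoate synthase dehydration, 17 heavy
atoms with full ring aromatization, cost 7) maps in a few seconds within a
2 000 000-node budget.  Mappings are memoized on the exact ordered graph
of both sides.

Bond changes are exactly the bonds present on one side and absent on the
other (formed/cleaved), present on both with different orders
(order-changed), or with different stereo flags (stereo-changed); an
order change suppresses the stereo comparison on that bond.  Atom-stereo
(R/S) flag flips are stereo-changed entries recorded with a single atom
coordinate — flag comparison only, not a geometric treatment, so a CIP
relabeling caused by remote substituent changes also registers.  Implicit
hydrogen-count changes are *not* bond changes; they are reported as
auxiliary `(h_delta, element, delta)` descriptors so proton transfers stay
visible to the similarity metrics.  The mapping cost equals the length of
the extracted change list by construction.

## Reaction similarity metrics

All three metrics are symmetric, bounded in [0, 1], with self-similarity
1.0 for non-degenerate reactions (an identity reaction has an empty change
set and scores 0.0 against everything, itself included).

Reversible and unknown-direction reactions are orientation-normalized
before comparison: the orientation whose sorted bond-change descriptor
multiset is lexicographically smaller is used (ties broken on component
canonical SMILES), so a reaction and its reverse produce identical scores.
Explicitly forward/backward reactions keep their stated direction.

* **Reaction center**: Tanimoto between circular fingerprints seeded only
  at reaction-center atoms (every atom participating in a change, on both
  sides via the mapping).  Substrate-side and product-side environments
  are pooled into one multiset with each feature tagged by side and by the
  change kinds its seed atom participates in, so a reaction and its
  reverse remain distinguishable when directionality is explicit.  This is
  the most nuanced metric: it sees both the changes and the chemical
  context in which they occur.
* **Bond change**: Tanimoto between environment-free multisets of change
  descriptors (kind + sorted element pair + orders, plus the hydrogen
  deltas).  Two reactions performing the same transformation on different
  scaffolds score 1.0.
* **Small molecule**: whole-molecule fingerprints of the chosen side
  (substrates, products, or the average of both) matched one-to-one by an
  optimal assignment (Hungarian algorithm) maximizing summed Tanimoto,
  normalized by the larger molecule count so unmatched molecules
  contribute zero.

Pairwise scores are stored in a flat store keyed by the unordered
reaction-id pair.

## Networks and concordance

A similarity network draws an edge wherever the pairwise score is >= the
threshold (inclusive, matching the "at least" reading); entities with no
passing edge stay as isolated nodes.  Ingested structure scores (e.g.
TM-score tables from external alignment tools) are used on their native
scale with no renormalization.  Clusters are connected components at the
chosen threshold — a deterministic proxy for visually tight groups.
Annotation tables attach subgroup/family/EC labels to nodes; a reaction
catalyzed by families in two subgroups carries both labels.

Concordance between an evolutionary labeling and a chemistry clustering is
reported as: adjusted Rand index over the common entity set; per-cluster
purity (multi-label entities count as correct if any label matches the
cluster majority; a fractional variant is available); and per-label edge
homophily — for label L, the fraction of edges touching an L-node whose
endpoints both carry L.  A label with no touching edges has undefined
homophily and is reported as null rather than zero.

Exports cover edge/node TSV, SIF (`source relation targets...`, isolated
nodes as bare ids) and a minimal XGMML subset; all formats re-import with
edge and attribute equality.

## The synthetic superfamily generator

The generator emulates the anatomy of a functionally diverse superfamily:
`n_subgroups` subgroups, each with monofunctional families, every family
catalyzing one reaction built from a scaffold (a small acid-sugar-like
chain with a family-specific tail from a 36-entry library) and a transform
from an eight-entry library (dehydration, ammonia elimination,
dehydrochlorination, racemization, cycloisomerization, lactonization,
tautomerization, decarboxylation).  Each transform is an explicit rewrite
emitted together with its exact bond-change descriptor multiset, giving
the mapping machinery a second, generator-side oracle.  All generated
reactions are atom balanced and carry an explicit forward direction (the
generator defines each transform left-to-right).

`chem_evo_agreement` is the probability that a family uses its subgroup's
designated transform instead of a uniformly random one; at 1.0 subgroup
membership predicts the chemistry exactly, at 0.0 they are independent.
The eight transforms have pairwise-distinct descriptor multisets with a
maximum between-transform bond-change similarity of 0.6, so the default
reaction-network threshold of 0.8 separates transforms while
within-transform pairs score exactly 1.0.  Structure similarity is
simulated, not computed from 3D (the structure pipeline of a real study
depends on external alignment tools and coordinate databases):
within-subgroup scores are drawn from N(0.90, 0.03) and between-subgroup
from N(0.35, 0.08), clipped to [0, 1], emulating a TM-score-like table in
which subgroups are cleanly resolved at the default structure threshold of
0.7.  Generation is reproducible: one `numpy` generator seeded from the
spec drives every draw, and bundles serialize byte-identically.

The planted-disconnect fixture assigns one subgroup two transforms that
are each the designated chemistry of another subgroup, so its reactions
split across two chemistry clusters populated by other subgroups, while a
control subgroup keeps a unique transform.  Subgroup edge homophily is
then strictly lower in the reaction network than in the structure network
for the split subgroup and equal for the control — the structural analogue
of a subgroup whose members scatter across a reaction-similarity map while
clustering tightly by structure.

What passing these tests shows — and does not show.  The generator's
reactions are small, fully balanced, stereo-sparse and free of cofactors,
protonation ambiguity and resonance edge cases; its structure scores are
draws from two well-separated normals, not alignments.  Passing therefore
demonstrates the correctness of the algorithms (mapping optimality,
change extraction, metric axioms, network construction, concordance
recovery), not the curation-grade behavior of the metrics on real
superfamily archives, where thresholds must be chosen per metric and per
dataset.

## Worked examples

Five curated reactions, encoded from standard textbook structures of the
named metabolites: muconate cycloisomerization (EC 5.5.1.1, MLE subgroup;
forms the ring C–O bond and demotes one C=C), mandelate racemization
(EC 5.1.2.2, MR; a single stereo change), gluconate dehydration
(EC 4.2.1.39, MR), the o-succinylbenzoate synthase dehydration
(EC 4.2.1.113, evolutionarily MLE yet chemically an EC 4.2.1 dehydration —
the classic disconnect case), and galactarate dehydration (EC 4.2.1.42),
the canonical example of one overall reaction shared by families in two
subgroups (GalD and MR), which therefore carries one annotation row per
family.

## Problem sizes and numerical choices

Default problem sizes used by the tests and the acceptance script:
exhaustive mapping verification on 16 reactions of <= 8 heavy atoms;
ground-truth recovery on 104 generated reactions; metric axioms on several
hundred random pairs; network oracle on 200-entity random matrices at 10
thresholds; concordance on 8 subgroups x 25 families (200 entities) over
seeded replicates.  These sizes resolve the tested properties while
keeping a full run at desk scale.

Tie-breaks and degenerate inputs: equal-cost mappings resolve to the
lexicographically smallest under canonical ranks; empty-vs-empty
fingerprints score 0; identity reactions have empty centers; unbalanced
reactions map to an explicit error; malformed EC strings become
"unassigned" labels rather than failures; unknown residue roles and
unlabeled network nodes are warnings, not errors.

## Known limitations

* Stereo handling is flag comparison, not geometry: atom-mapping does not
  search over stereo assignments, and remote-induced CIP relabeling counts
  as a stereo change.
* The mapping search is exact but exponential in the worst case; the
  budget makes failure explicit.  Beyond ~20 heavy atoms with high
  symmetry, expect budget errors rather than slow answers.
* Reaction-center fingerprint choices (radius, side pooling, change-kind
  tagging) are declared defaults of this implementation; absolute score
  values are not comparable with other reaction-similarity tools, so
  thresholds must be re-chosen per metric rather than transferred.
* Multi-domain proteins are counted per functional domain, not per
  protein, in all statistics.
* The toolkit ingests structure-similarity tables; it never computes
  structural alignments, sequence similarity or MSAs.
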