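# Methods

This note documents the models and procedures implemented in `rvdesign`,
the parameters that matter, the synthetic study conditions the tests run
under, and the numerical conventions and known limitations.

## Atom-pair descriptors and reaction vectors

Molecules are described by multisets of typed heavy-atom paths:

* **AP2** — every bond between two heavy atoms;
* **AP3** — every angle (simple path of three heavy atoms).

Atoms are typed by *(element, heavy-atom degree, π count)*. The π count
is the number of π electrons on the atom: one per double bond, two per
triple bond, and exactly one for an aromatic atom regardless of its ring
bond count (an exocyclic double bond adds on top). Aromatic bonds carry
a distinct bond-order token, so Kekulé and aromatic forms never collide.
Hydrogens are never typed; degree is measured on the parent molecule,
not along the path, which makes the descriptors substitution-sensitive.
Each path feature is stored in its canonical orientation — the
lexicographically smaller of the two readings — giving deterministic
multiset keys. Descriptors are additive over disconnected components
(no cross-component paths), so a multi-component input is simply the sum
of its parts.

A **reaction vector** is `products − reactants` on these multisets,
stored as a disjoint negative part (features lost) and positive part
(features gained). Conservation is exact by construction and asserted
in tests: `positive − negative` equals the full signed difference.
**Applicability** is count-aware multiset containment of the negative
part in the starting material (plus reagent, when supplied); a binary
reading would accept infeasible double substitutions, so multiplicity is
always honoured.

Because AP3 features reach two bonds from every changed atom, a vector
transfers only to molecules whose reaction-centre environment matches to
that radius. This is intended behaviour, not a defect: it is why
realistic vector collections contain many thousands of vectors per
reaction class.

## Structure generation

Applying a vector is a bounded search over bond edits on the combined
starting-material + reagent graph:

* **moves** — delete a bond whose current AP2 feature is lost by the
  vector; change such a bond's order to one occurring in the positive
  part; form a bond between atoms whose current type occurs in the
  negative AP2 part (isolated atoms such as ammonia are admitted by
  element), with an order from the positive part;
* **bounds** — deletions ≤ total negative AP2 count, formations ≤ total
  positive AP2 count, total edits ≤ 4;
* **screening** — for each candidate edit set the AP2 delta is predicted
  symbolically (degrees and π counts updated without building a
  molecule); only AP2-exact candidates are built, re-sanitized, and
  accepted iff the full AP2+AP3 descriptor change equals the vector;
* **ordering** — edit sets are enumerated by increasing total edit
  count, form-light splits first, and the search stops at the first
  split that yields products: larger edit sets reproducing the same
  descriptor change are redundant decorations of the same
  transformation. Products are deduplicated by canonical SMILES and
  returned in canonical order, capped at `max_products` (default 8).

By-products are implicit: the identity is checked over all fragments of
the edited graph and the fragment holding the former starting-material
core (most starting-material atoms, ties to the larger fragment) is
reported as the product. Touched atoms have charges and explicit
hydrogen counts reset so RDKit refills valences — this is how a nitro
group's oxygens leave as water in a reduction.

Two structural assumptions bound the search: reaction-centre feature
losses and gains must not mutually cancel between distinct centres, and
aromatic ring bonds are never edited (ring-forming/opening chemistry is
out of scope). Both hold for the packaged reaction families.

## Reaction classes

Labels live in a four-level hierarchy written
`Level1 (Level2) (Level3) (Level4)`. Truncation to a shallower level
merges subclasses; matching at a level compares truncations. En-dashes
are normalised to hyphens and whitespace collapsed on parse, since the
textual forms in circulation mix typography. Label vocabularies are
data-driven: nothing about the class names is hard-coded.

## Training data

Starting materials are extracted from classified reactions by the
most-mapped-atoms rule; a tie is a discard (counted and reported), and a
multi-reactant reaction without maps is an error. Labels are truncated
to the working level and exact (InChIKey, class) duplicates dropped —
the full key, not a prefix. Fingerprinted entries are **pivoted**:
identical fingerprints merge into one entry with the union of labels.
Coarser schemes therefore produce smaller datasets; the functional-group
dictionary merges strictly more than MACCS on the packaged data, and the
pivot conserves mass (Y-matrix total equals the number of distinct
(fingerprint, label) pairs).

The stratified 80/20 split groups entries by label count. Counts of
five or more are pooled into one stratum — tiny strata are unsplittable
— and singleton strata go to the training side. Each stratum is split
to within one entry of the target fraction; the split is reproducible
under its seed.

## Recommender

Four problem transformations over a pluggable base learner:

* **BR** — one independent binary learner per label;
* **CC** — chain in vocabulary order (configurable permutation); link
  *i* is trained on the features plus the *true* labels of earlier
  links and fed its own *predictions* at inference, the standard
  classifier-chain construction. With a base learner blinded to the
  appended columns, CC collapses to BR exactly (tested);
* **RAkELd** — a seeded random permutation of the vocabulary is chopped
  into disjoint subsets of size *k* (default 3); one label-powerset
  multi-class learner per subset;
* **RAkELo** — `model_count` (default 2·|vocabulary|) distinct random
  subsets of size *k*, overlap allowed; a label is predicted positive
  iff strictly more than half of its covering subsets vote yes, and a
  label covered by no subset is negative. The vote threshold is this
  package's convention.

Bundled base learners: a random forest (10 gini trees, sqrt features,
bootstrap) and a linear-margin classifier (squared hinge, C = 1,
max_iter = 1000), both seeded. A label with no positive (or no
negative) training example gets a constant stub learner. An empty
prediction set is meaningful — *no recommendation* — and downstream
design treats it as "apply no filter".

Micro metrics are computed from globally pooled TP/FP/FN/TN; zero
denominators yield 0 so the metrics are total. The three-outcome
evaluation scores an entry correct when the recommendation set contains
the annotated class at the comparison level, no-recommendation when the
set is empty, wrong otherwise; the three percentages partition 100% and
coarsening the level can only preserve or raise the correct rate.

## Design and RENATE

Vector filtering keeps the vectors whose class matches any recommended
label at the working level. Unlabelled vectors are retained by default
(`drop_unlabelled=False`): real vector collections are only partially
classified, and dropping them would silently cripple runs. Filtering
only ever removes vectors, so a filtered library is a subset of the
control library, and generalising labels (level 3 → 1) monotonically
grows the applicable-vector set.

RENATE parameters (defaults): `min_fragment_atoms=5` — BRICS candidate
bonds are cut greedily in deterministic order only while both pieces
keep at least five heavy atoms; `analogs_per_fragment=1000` — nearest
pool members by 1024-bit radius-2 Morgan count fingerprints under
Euclidean distance, with the dummy-stripped fragment itself injected so
an exact pool match ranks first at distance zero; `beam_width=25` — the
products closest to the reference that survive between assembly
iterations. Fragments are ranked by (attachment points, heavy atoms)
descending and the first is the scaffold, so assembly grows from the
most connected piece outward. Each iteration combines the current set
with the next fragment's analogs in both starting-material/reagent
orientations; the recommendation is always taken for the growing
scaffold member; products are scored by count-fingerprint distance to
the reference (ascending, ties by canonical id). The whole beam reacts
with the next fragment set — restricting to scaffold-containing members
is a conceivable alternative this package does not take. Rediscovery
means the reference's InChIKey appears among the generated products; an
empty intermediate product set stops the run unrediscovered.

## Synthetic study conditions

The fixture generator emulates the statistical structure of a
patent-derived training corpus at desk scale: nine templated reaction
classes (amide coupling, esterification, N-alkylation, Williamson
etherification, Suzuki coupling, Boc protection and deprotection, nitro
reduction, alkene hydrogenation) over pools of roughly 10–30 starting
materials per functional family, sampled under a skewed class
distribution (C–N bond formation ≈ 35% at level 1, functional
conversion ≈ 20%, deprotection ≈ 13%, the rest small). Reactions are
born mapped and carbon-balanced with by-products recorded; map numbers
are kept only for atoms reaching the main product, mirroring corpora in
which by-products go unrecorded, which is what makes the most-mapped
starting-material rule meaningful.

Key deliberate features: the same starting materials recur under several
classes (acids feed amide and ester condensations; amines feed
alkylation and Boc protection), so pivoting yields genuine multi-label
entries; and a competing-functionality family of amino-alcohol alkenes
carries only Functional Conversion and Protection labels — molecules
bearing both an NH and an OH never appear under coupling/condensation
classes, so a trained recommender never suggests those classes for such
molecules. Because each family's label set is a deterministic function
of its functional groups, held-out recovery is near-perfect (micro
F1 ≥ 0.9 for every strategy); this shows the pipeline is correct, not
that real patent-scale data — with its label noise, class overlap and
domain drift — would score similarly. Real-corpus micro F1 for
comparable recommenders sits far lower.

The RENATE fixture is a three-fragment amide/ether target
(`O=C(NCCc1ccc(OCc2ccccc2)cc1)C1CCCC1`) whose BRICS cleavages meet the
five-atom minimum, with a pool of its three building blocks plus ≥ 50
family decoys. Its vector set is deliberately only partially labelled —
the two join vectors are unlabelled, the decoys labelled — exercising
the unlabelled-retention rule while letting the recommender prune decoy
chemistry (≈ 46% fewer products at unchanged rediscovery on the packaged
case).

Problem sizes used by the test suite and the acceptance script — 2000
sampled reactions for training (≈ 90 pivoted entries, 9 classes), 220
reactions for the round-trip corpus, a 55-molecule RENATE pool — are the
package's study conditions; they keep a full run around a minute on one
CPU.

## Numerical conventions and degenerate inputs

* Zero-count multiset entries are never stored; multiset equality is
  exact integer equality.
* Canonical identifiers are full InChIKeys of map-stripped structures.
* All randomness flows through `numpy.random.default_rng` seeds carried
  in configs; identical inputs and seeds give identical models,
  predictions, libraries and RENATE output.
* Empty molecule → empty descriptor multiset (not an error); identity
  reaction → identity vector, whose application returns the input.
* Balancing rejects carbon imbalance with a reason code rather than an
  exception; the missing-fragment dictionary (water, hydrogen halides,
  boronic residue) only settles non-carbon bookkeeping. Isomeric
  alternative products (same formula, each carbon-matching the
  reactants) split into one reaction per product.
* Model serialization refuses to load on version-tag mismatch.

## Known limitations

* The edit search models neutral organic chemistry; formal charges on
  touched atoms are reset, so zwitterionic or organometallic centres are
  out of scope, as are stereochemistry-aware vectors.
* Vectors cannot describe ring aromatisation or aromatic ring cleavage
  (aromatic bonds are never edited).
* The fixture families are clean by design: no atom-mapping noise, no
  mislabelled classes, no unbalanced source reactions. Pipeline
  behaviour under such noise is untested here.
* Synthetic-accessibility scoring is an external-scorer hook
  (name → callable); no scorer is bundled.
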