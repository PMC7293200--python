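# rvdesign

Reaction-based de novo design with a multi-label **Reaction Class
Recommender**. The package is aimed at computational and medicinal
chemists who want generated structures to stay close to known synthetic
chemistry: transformations are encoded automatically from reaction data
as *reaction vectors*, and a recommender trained on starting-material
fingerprints filters which reaction classes are applied to each molecule
during enumeration.

## The method

**Reaction vectors.** A molecule is summarised as a multiset of typed
atom-pair path descriptors: AP2 features (one bond, two heavy atoms) and
AP3 features (two bonds, three heavy atoms), with atoms typed by the
triple *(element, heavy-atom degree, π-electron count)*. For a balanced
reaction the vector is the signed difference

```
v = Σ descriptors(products) − Σ descriptors(reactants)
```

split into a *negative* part (features lost from the reactants) and a
*positive* part (features gained in the products). A vector is
**applicable** to a starting material *S*, optionally combined with a
reagent *R*, when its negative features are wholly present — with
multiplicity — in descriptors(S) (+ descriptors(R)). Applying a vector
searches bounded combinations of bond edits (break / form / order
change) on the reaction-centre atoms and accepts exactly those whose
descriptor change reproduces *v*; by-products (water, HBr, …) fall out of
the same bookkeeping.

**The recommender.** Because vectors see only the reaction centre, they
are blind to competing functionality elsewhere in the molecule (a free
NH next to a free OH, say). The recommender closes that gap: starting
materials from classified reactions are fingerprinted with whole-molecule
schemes (MACCS keys, Avalon hashed fingerprints, feature-Morgan,
functional-group keys), identical fingerprints are merged into single
entries carrying the union of their reaction-class labels, and the
resulting multi-label problem is solved by problem transformation —
Binary Relevance, Classifier Chains, or the RAkELd/RAkELo label-powerset
ensembles — over random-forest or linear-SVM base learners. Classes live
in a four-level hierarchy (`C-C Bond Formation (Coupling) (Suzuki)
(Bromo)`), so recommendations can be generalised by truncating labels.
An empty prediction means *no recommendation*: the design step then
applies no filter. Evaluation uses micro-averaged recall/precision/F1
from globally pooled confusion counts, plus a three-outcome bookkeeping
(correct / wrong / no-recommendation) against annotated classes.

**Design modes.** `single_step_enumerate` scans vectors against each
starting material (alone and with each reagent) and collects every
generated product, optionally filtered by the recommendation. `renate_run`
is a pseudo-retrosynthetic mode: a reference molecule is cleaved at BRICS
bonds (minimum fragment size five heavy atoms), analogs of each fragment
are retrieved from a reagent pool by Morgan count-fingerprint Euclidean
distance, and the fragment analog sets are reassembled combinatorially
through applicable vectors, keeping a beam of the products closest to the
reference between iterations.

Everything is testable offline: `rvdesign.fixtures` generates classified,
mapped, carbon-balanced reactions from nine templated reaction classes
with a skewed class distribution, competing-functionality cases, and a
three-fragment RENATE rediscovery target.

## Worked example

```python
from rdkit import Chem
from rvdesign import (parse_reaction_smiles, compute_reaction_vector,
                      is_applicable, apply_reaction_vector, mol_from_smiles)

rxn = parse_reaction_smiles("CCC(=O)O.NCCc1ccccc1>>CCC(=O)NCCc1ccccc1.O")
rv = compute_reaction_vector(rxn, id="amide")
print(f"lost features:   {len(rv.negative)}")
print(f"gained features: {len(rv.positive)}")

sm = mol_from_smiles("CCCC(=O)O")          # butyric acid
amine = mol_from_smiles("NCCc1ccc(F)cc1")  # 4-fluorophenethylamine
print("applicable:", is_applicable(rv, sm, amine))
for product in apply_reaction_vector(rv, sm, amine):
    print("product:", Chem.MolToSmiles(product))
```

prints

```
lost features:   5
gained features: 6
applicable: True
product: CCCC(=O)NCCc1ccc(F)cc1
```

The vector derived from one amide coupling transfers to a new acid/amine
pair whose reaction-centre environment matches: the five lost features
(the acid C–OH bond, the amine C–N feature and their angles) are present
in the new pair, and the bounded edit search regenerates the amide plus
water, returning the amide as the product. Note that transfer is
environment-specific — the same vector is *not* applicable to, say,
acetic acid, whose α-carbon environment differs.

A complete pipeline — fixture generation, recommender training,
filtered design and RENATE — is exposed on the command line:

```bash
rvdesign fixtures --n 500 --seed 1 --out fx/
rvdesign train --data fx/reactions.csv --scheme maccs --strategy cc --level 3 --seed 11 --out model/
rvdesign recommend --model model/ --smiles-file my_starting_materials.smi
rvdesign renate --ref "$(cat fx/renate_target.smi)" --pool fx/pool.smi --rvs fx/vectors.json --model model/ --out library.csv
```

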