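"""Multi-label training data built from classified reactions.

Starting materials are extracted from labelled reactions (most-mapped
reactant; ties discarded), labels are truncated to the working level of
the class hierarchy, and exact (structure, class) duplicates are removed.
Entries are then fingerprinted and *pivoted*: starting materials with
identical fingerprints are merged into a single entry whose label set is
the union of their classes.  The pivoted entries materialise directly
into the binary feature matrix X and label matrix Y used by the
recommender.

Because pivoting operates on descriptors, coarser fingerprint schemes
merge more aggressively and yield smaller datasets — the number of
entries is a property of the (data, scheme) pair, not of the data alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem

from .descriptors import BitFingerprint, binary_fingerprint, mol_from_smiles
from .labels import LabelVocabulary, ReactionClassLabel, truncate_label
from .reactions import Reaction, select_starting_material

__all__ = [
    "LabeledStartingMaterial",
    "TrainingEntry",
    "MultiLabelDataset",
    "canonical_id",
    "build_labeled_entries",
    "pivot_merge",
    "stratified_split",
    "read_classified_csv",
    "summarize",
]


def canonical_id(mol: Chem.Mol) -> str:
    """InChIKey of the map-stripped structure (full key)."""
    clean = Chem.Mol(mol)
    for atom in clean.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToInchiKey(clean)


@dataclass(frozen=True)
class LabeledStartingMaterial:
    structure: Chem.Mol
    canonical_id: str
    label: ReactionClassLabel


@dataclass(frozen=True)
class TrainingEntry:
    fingerprint: BitFingerprint
    labels: FrozenSet[ReactionClassLabel]
    member_count: int

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("entry label set must be non-empty")
        depths = {l.depth for l in self.labels}
        # labels sit at one working level; shallower natural depth is fine
        if self.member_count < 1:
            raise ValueError("member_count must be >= 1")


@dataclass
class MultiLabelDataset:
    entries: List[TrainingEntry]
    vocabulary: LabelVocabulary
    X: np.ndarray
    Y: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.entries) or self.Y.shape[0] != len(self.entries):
            raise ValueError("X/Y rows must align with entries")
        if self.Y.size and not self.Y.any(axis=1).all():
            raise ValueError("every entry must have at least one positive label")

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, indices: Sequence[int]) -> "MultiLabelDataset":
        idx = list(indices)
        return MultiLabelDataset(
            entries=[self.entries[i] for i in idx],
            vocabulary=self.vocabulary,
            X=self.X[idx],
            Y=self.Y[idx],
            scheme=self.scheme,
        )


def build_labeled_entries(
    rxns: Iterable[Reaction], level: int
) -> Tuple[List[LabeledStartingMaterial], Dict[str, int]]:
    """Extract, truncate and deduplicate (starting material, class) pairs.

    Returns the entries plus a report of how many inputs were discarded
    (unlabelled, ambiguous starting material) or removed as duplicates.
    """
    report = {"input": 0, "unlabelled": 0, "ambiguous_sm": 0, "duplicate": 0}
    seen: set = set()
    out: List[LabeledStartingMaterial] = []
    for rxn in rxns:
        report["input"] += 1
        if rxn.label is None:
            report["unlabelled"] += 1
            continue
        sm = select_starting_material(rxn)
        if sm is None:
            report["ambiguous_sm"] += 1
            continue
        label = truncate_label(rxn.label, level)
        cid = canonical_id(sm)
        key = (cid, label)
        if key in seen:
            report["duplicate"] += 1
            continue
        seen.add(key)
        out.append(LabeledStartingMaterial(sm, cid, label))
    return out, report


def pivot_merge(
    entries: Sequence[LabeledStartingMaterial], scheme: str
) -> MultiLabelDataset:
    """Merge entries with identical fingerprints, unioning their labels."""
    groups: Dict[FrozenSet[int], Dict] = {}
    order: List[FrozenSet[int]] = []
    fps: Dict[FrozenSet[int], BitFingerprint] = {}
    for e in entries:
        fp = binary_fingerprint(e.structure, scheme)
        key = fp.on_bits
        if key not in groups:
            groups[key] = {"labels": set(), "members": set()}
            order.append(key)
            fps[key] = fp
        groups[key]["labels"].add(e.label)
        groups[key]["members"].add(e.canonical_id)

    all_labels = {l for g in groups.values() for l in g["labels"]}
    level = max((l.depth for l in all_labels), default=1)
    vocab = LabelVocabulary.from_labels(all_labels, level)
    label_index = {l: i for i, l in enumerate(vocab.labels)}

    merged = [
        TrainingEntry(
            fingerprint=fps[key],
            labels=frozenset(groups[key]["labels"]),
            member_count=len(groups[key]["members"]),
        )
        for key in order
    ]
    n_bits = fps[order[0]].n_bits if order else 0
    X = np.zeros((len(merged), n_bits), dtype=np.uint8)
    Y = np.zeros((len(merged), len(vocab)), dtype=np.uint8)
    for i, entry in enumerate(merged):
        if entry.fingerprint.on_bits:
            X[i, sorted(entry.fingerprint.on_bits)] = 1
        for l in entry.labels:
            Y[i, label_index[l]] = 1
    return MultiLabelDataset(entries=merged, vocabulary=vocab, X=X, Y=Y, scheme=scheme)


def stratified_split(
    ds: MultiLabelDataset,
    train_fraction: float,
    seed: int,
    stratum_cap: int = 5,
) -> Tuple[MultiLabelDataset, MultiLabelDataset]:
    """Split by label-count strata to train/test fractions.

    Entries are grouped by the number of labels they carry (counts of
    ``stratum_cap`` or more are pooled: tiny strata are unsplittable);
    each stratum is split to within one entry of the target fraction.
    Singleton strata go to the training side.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strata: Dict[int, List[int]] = {}
    for i, e in enumerate(ds.entries):
        k = min(len(e.labels), stratum_cap)
        strata.setdefault(k, []).append(i)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for k in sorted(strata):
        idx = np.array(strata[k])
        rng.shuffle(idx)
        if len(idx) == 1:
            train_idx.extend(idx.tolist())
            continue
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    return ds.subset(sorted(train_idx)), ds.subset(sorted(test_idx))


def read_classified_csv(path: str) -> List[Reaction]:
    """Read reactions from CSV with columns (rxn_smiles, label) or (smiles, label)."""
    from .reactions import parse_reaction_smiles  # local import avoids cycle
    from .labels import parse_label

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    out: List[Reaction] = []
    if "rxn_smiles" in cols:
        for _, row in df.iterrows():
            out.append(
                parse_reaction_smiles(row[cols["rxn_smiles"]], label=row[cols["label"]])
            )
    elif "smiles" in cols:
        for _, row in df.iterrows():
            mol = mol_from_smiles(row[cols["smiles"]])
            out.append(
                Reaction(
                    reactants=[mol],
                    products=[Chem.Mol(mol)],
                    label=parse_label(row[cols["label"]]),
                )
            )
    else:
        raise ValueError("CSV needs a rxn_smiles or smiles column")
    return out


def summarize(ds: MultiLabelDataset) -> Dict[str, float]:
    """Entries, classes and per-class example statistics."""
    per_class = ds.Y.sum(axis=0)
    return {
        "entries": len(ds),
        "classes": len(ds.vocabulary),
        "median_examples_per_class": float(np.median(per_class)) if per_class.size else 0.0,
        "mean_examples_per_class": float(per_class.mean()) if per_class.size else 0.0,
        "mean_labels_per_entry": float(ds.Y.sum(axis=1).mean()) if len(ds) else 0.0,
    }
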