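"""Reactions, balancing, starting-material selection and reaction vectors.

A reaction vector is the signed difference between the atom-pair
descriptor multisets of the product side and the reactant side of a
balanced reaction: the *negative* part collects the features lost from
the reactants, the *positive* part the features gained in the products.
A vector is applicable to a starting material (optionally combined with a
reagent) when its negative features are wholly present, count-aware, in
the combined descriptor multiset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from rdkit import Chem

from .descriptors import DescriptorMultiset, mol_from_smiles, molecule_descriptor
from .labels import ReactionClassLabel, parse_label

__all__ = [
    "Reaction",
    "ReactionVector",
    "BalanceResult",
    "parse_reaction_smiles",
    "reaction_to_smiles",
    "balance_reaction",
    "select_starting_material",
    "compute_reaction_vector",
    "is_applicable",
    "vectors_to_json",
    "vectors_from_json",
]


@dataclass
class Reaction:
    """Reactants and products as RDKit molecules, plus an optional label.

    Atom correspondence is carried by atom map numbers on the molecules;
    a map number present on a reactant atom and a product atom identifies
    the same atom on both sides.
    """

    reactants: List[Chem.Mol]
    products: List[Chem.Mol]
    label: Optional[ReactionClassLabel] = None

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise ValueError("a reaction needs at least one reactant and one product")

    def carbon_counts(self) -> Tuple[int, int]:
        def carbons(mols: Sequence[Chem.Mol]) -> int:
            return sum(
                1 for m in mols for a in m.GetAtoms() if a.GetAtomicNum() == 6
            )

        return carbons(self.reactants), carbons(self.products)

    def reactant_descriptor(self) -> DescriptorMultiset:
        total = DescriptorMultiset()
        for m in self.reactants:
            total = total + molecule_descriptor(m)
        return total

    def product_descriptor(self) -> DescriptorMultiset:
        total = DescriptorMultiset()
        for m in self.products:
            total = total + molecule_descriptor(m)
        return total


def parse_reaction_smiles(
    text: str, label: Optional[str | ReactionClassLabel] = None
) -> Reaction:
    """Parse ``reactants>agents>products`` reaction SMILES (agents dropped)."""
    parts = text.split(">")
    if len(parts) != 3:
        raise ValueError(f"not a reaction SMILES: {text!r}")
    reactants = [mol_from_smiles(s) for s in parts[0].split(".") if s]
    products = [mol_from_smiles(s) for s in parts[2].split(".") if s]
    if isinstance(label, str):
        label = parse_label(label)
    return Reaction(reactants=reactants, products=products, label=label)


def reaction_to_smiles(rxn: Reaction) -> str:
    lhs = ".".join(Chem.MolToSmiles(m) for m in rxn.reactants)
    rhs = ".".join(Chem.MolToSmiles(m) for m in rxn.products)
    return f"{lhs}>>{rhs}"


# Small-molecule fragments that may be inserted to settle non-carbon
# bookkeeping during balancing (leaving groups the source data tends to
# omit).  Keys are element-count signatures.
_INSERTABLE = {
    "O": "O",        # water
    "F": "F",        # hydrogen fluoride
    "Cl": "Cl",
    "Br": "Br",
    "I": "I",
    "BOO": "OBO",    # boronic-acid residue
}


@dataclass
class BalanceResult:
    """Outcome of balancing: zero or more balanced reactions, or a reason."""

    reactions: List[Reaction]
    reason: Optional[str] = None

    @property
    def rejected(self) -> bool:
        return not self.reactions


def _formula_signature(mol: Chem.Mol) -> str:
    symbols = sorted(a.GetSymbol() for a in mol.GetAtoms())
    return "".join(symbols)


def _element_deficit(rxn: Reaction) -> Dict[str, int]:
    """reactant-side minus product-side heavy-atom counts per element."""
    counts: Dict[str, int] = {}
    for m in rxn.reactants:
        for a in m.GetAtoms():
            counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) + 1
    for m in rxn.products:
        for a in m.GetAtoms():
            counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) - 1
    return {k: v for k, v in counts.items() if v != 0}


def balance_reaction(rxn: Reaction) -> BalanceResult:
    """Carbon-balance a reaction, splitting isomeric alternative products.

    A multi-product reaction in which each product alone carbon-balances
    the reactant side (isomeric alternatives) is split into one reaction
    per product.  Missing small leaving groups (water, hydrogen halides,
    boronic residues) are appended to the deficient side.  Reactions whose
    carbon counts cannot be reconciled are rejected with a reason code.
    """
    if not rxn.reactants or not rxn.products:
        raise ValueError("empty reaction side")
    rc, pc = rxn.carbon_counts()
    if rc != pc:
        # isomeric alternatives: several products, each matching the
        # reactant carbon count on its own
        if len(rxn.products) > 1:
            per_product = [
                sum(1 for a in p.GetAtoms() if a.GetAtomicNum() == 6)
                for p in rxn.products
            ]
            if all(c == rc for c in per_product):
                sigs = {_formula_signature(p) for p in rxn.products}
                if len(sigs) == 1:
                    return BalanceResult(
                        [
                            Reaction(
                                [Chem.Mol(m) for m in rxn.reactants], [p], rxn.label
                            )
                            for p in rxn.products
                        ]
                    )
        # the insertion dictionary is carbon-free by construction, so a
        # carbon imbalance cannot be repaired
        return BalanceResult([], reason="carbon_imbalance")
    # carbons agree; settle non-carbon bookkeeping by appending known
    # small leaving groups to the deficient (product) side
    deficit = _element_deficit(rxn)
    missing = {k: v for k, v in deficit.items() if v > 0}
    insertions = []
    for elem, n in sorted(missing.items()):
        frag = _INSERTABLE.get(elem)
        if frag:
            insertions.extend(mol_from_smiles(frag) for _ in range(n))
    if not insertions:
        return BalanceResult([rxn])
    patched_products = [Chem.Mol(m) for m in rxn.products] + insertions
    return BalanceResult(
        [Reaction([Chem.Mol(m) for m in rxn.reactants], patched_products, rxn.label)]
    )


def _mapped_atom_count(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomMapNum() > 0)


def select_starting_material(rxn: Reaction) -> Optional[Chem.Mol]:
    """The reactant with strictly the most mapped atoms; ties discard.

    Returns None for the discard signal.  A multi-reactant reaction
    without any atom map cannot be disambiguated and raises.
    """
    if len(rxn.reactants) == 1:
        return rxn.reactants[0]
    counts = [_mapped_atom_count(m) for m in rxn.reactants]
    if all(c == 0 for c in counts):
        raise ValueError("multiple reactants but no atom map")
    best = max(counts)
    if counts.count(best) > 1:
        return None
    return rxn.reactants[counts.index(best)]


@dataclass
class ReactionVector:
    """Lost (negative) and gained (positive) atom-pair features."""

    negative: DescriptorMultiset
    positive: DescriptorMultiset
    source_label: Optional[ReactionClassLabel] = None
    id: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.negative.counts) & set(self.positive.counts)
        if overlap:
            raise ValueError("negative and positive supports must be disjoint")
        if any(v <= 0 for v in self.negative.counts.values()) or any(
            v <= 0 for v in self.positive.counts.values()
        ):
            raise ValueError("stored counts must be positive")

    @property
    def is_identity(self) -> bool:
        return not self.negative and not self.positive

    def delta(self) -> DescriptorMultiset:
        """positive - negative, the exact descriptor change of the reaction."""
        return self.positive - self.negative


def compute_reaction_vector(rxn: Reaction, id: str = "") -> ReactionVector:
    """Product descriptors minus reactant descriptors, split by sign."""
    rc, pc = rxn.carbon_counts()
    if rc != pc:
        raise ValueError(f"unbalanced reaction: {rc} vs {pc} carbons")
    diff = rxn.product_descriptor() - rxn.reactant_descriptor()
    return ReactionVector(
        negative=diff.negative_part(),
        positive=diff.positive_part(),
        source_label=rxn.label,
        id=id,
    )


def is_applicable(
    rv: ReactionVector,
    sm: Chem.Mol,
    reagent: Optional[Chem.Mol] = None,
    sm_descriptor: Optional[DescriptorMultiset] = None,
    reagent_descriptor: Optional[DescriptorMultiset] = None,
) -> bool:
    """Count-aware containment of the negative features in sm (+ reagent).

    Precomputed descriptors may be passed to avoid recomputation in
    enumeration loops.
    """
    avail = sm_descriptor if sm_descriptor is not None else molecule_descriptor(sm)
    if reagent is not None or reagent_descriptor is not None:
        extra = (
            reagent_descriptor
            if reagent_descriptor is not None
            else molecule_descriptor(reagent)
        )
        avail = avail + extra
    return avail.contains(rv.negative)


def vectors_to_json(rvs: Sequence[ReactionVector]) -> str:
    payload = [
        {
            "id": rv.id,
            "label": str(rv.source_label) if rv.source_label else None,
            "negative": json.loads(rv.negative.to_json()),
            "positive": json.loads(rv.positive.to_json()),
        }
        for rv in rvs
    ]
    return json.dumps(payload, indent=1)


def vectors_from_json(text: str) -> List[ReactionVector]:
    out = []
    for item in json.loads(text):
        out.append(
            ReactionVector(
                negative=DescriptorMultiset.from_json(json.dumps(item["negative"])),
                positive=DescriptorMultiset.from_json(json.dumps(item["positive"])),
                source_label=parse_label(item["label"]) if item.get("label") else None,
                id=item.get("id", ""),
            )
        )
    return out
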