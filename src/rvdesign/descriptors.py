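"""Atom-pair path descriptors and whole-molecule fingerprints.

The reaction-vector machinery lives on *atom pair* descriptors: typed
heavy-atom paths of length 2 (AP2, one bond) and 3 (AP3, an angle).  Atoms
are typed Carhart-style by the triple (element, heavy-atom degree, pi
electron count); hydrogens are never typed.  A molecule is summarised as a
multiset of canonical path features, and a reaction as the signed
difference of product and reactant multisets.

Whole-molecule fingerprints (used as recommender features and for analog
retrieval) are exposed through a small registry so that the recommender can
be trained on interchangeable schemes: a structural-key dictionary
(MACCS), hashed path fingerprints (Avalon at 1024/2048/4096 bits),
feature-typed circular fingerprints (FeatMorgan) and a functional-group
SMARTS dictionary.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, Mapping, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

__all__ = [
    "AtomType",
    "PathFeature",
    "DescriptorMultiset",
    "BitFingerprint",
    "CountFingerprint",
    "type_atom",
    "path_descriptor_multiset",
    "molecule_descriptor",
    "binary_fingerprint",
    "count_fingerprint",
    "count_distance",
    "registered_schemes",
    "mol_from_smiles",
]

# Bond order tokens; aromatic is a distinct order so that aromatic and
# Kekule single/double bonds never collide in a path feature.
_ORDER_TOKEN = {
    Chem.BondType.SINGLE: "1",
    Chem.BondType.DOUBLE: "2",
    Chem.BondType.TRIPLE: "3",
    Chem.BondType.AROMATIC: "a",
}
_PI_CONTRIB = {"1": 0, "2": 1, "3": 2, "a": 1}


@dataclass(frozen=True, order=True)
class AtomType:
    """Carhart-style atom type: element, heavy-atom degree, pi count."""

    element: str
    heavy_degree: int
    pi_count: int

    def __post_init__(self) -> None:
        if self.heavy_degree < 0 or self.pi_count < 0:
            raise ValueError("heavy_degree and pi_count must be non-negative")

    def __str__(self) -> str:
        return f"{self.element}({self.heavy_degree},{self.pi_count})"


def _bond_token(bond: Chem.Bond) -> str:
    try:
        return _ORDER_TOKEN[bond.GetBondType()]
    except KeyError:
        raise ValueError(f"unsupported bond type: {bond.GetBondType()}")


def type_atom(mol: Chem.Mol, atom_index: int) -> AtomType:
    """Type a heavy atom on its parent molecule.

    Aromatic atoms count one pi electron for the aromatic system plus any
    further pi electrons from non-aromatic multiple bonds (e.g. an
    exocyclic double bond); aliphatic atoms sum pi electrons over their
    double/triple bonds.
    """
    if atom_index < 0 or atom_index >= mol.GetNumAtoms():
        raise ValueError(f"atom index {atom_index} out of range")
    atom = mol.GetAtomWithIdx(atom_index)
    if atom.GetAtomicNum() <= 1:
        raise ValueError("hydrogens are not typed")
    degree = sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1)
    pi = 1 if atom.GetIsAromatic() else 0
    for bond in atom.GetBonds():
        token = _bond_token(bond)
        if token == "a":
            continue  # covered by the single aromatic-system electron
        pi += _PI_CONTRIB[token]
    return AtomType(atom.GetSymbol(), degree, pi)


@dataclass(frozen=True, order=True)
class PathFeature:
    """A canonically oriented heavy-atom path of 2 (AP2) or 3 (AP3) atoms."""

    kind: str  # "AP2" | "AP3"
    atom_types: Tuple[AtomType, ...]
    bond_orders: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("AP2", "AP3"):
            raise ValueError("kind must be AP2 or AP3")
        if len(self.bond_orders) != len(self.atom_types) - 1:
            raise ValueError("bond_orders must be one shorter than atom_types")

    def canonical(self) -> "PathFeature":
        fwd = (self.atom_types, self.bond_orders)
        rev = (self.atom_types[::-1], self.bond_orders[::-1])
        if rev < fwd:
            return PathFeature(self.kind, *rev)
        return self

    def __str__(self) -> str:
        parts = [str(self.atom_types[0])]
        for order, at in zip(self.bond_orders, self.atom_types[1:]):
            parts.append(order)
            parts.append(str(at))
        return f"{self.kind}:" + "-".join(parts)


def _feature_from_string(text: str) -> PathFeature:
    kind, _, body = text.partition(":")
    tokens = body.split("-")
    atom_types = []
    orders = []
    for i, tok in enumerate(tokens):
        if i % 2 == 0:
            elem, rest = tok.split("(")
            d, p = rest.rstrip(")").split(",")
            atom_types.append(AtomType(elem, int(d), int(p)))
        else:
            orders.append(tok)
    return PathFeature(kind, tuple(atom_types), tuple(orders))


class DescriptorMultiset:
    """Signed integer counts over path features; zero entries are dropped."""

    __slots__ = ("counts",)

    def __init__(self, counts: Mapping[PathFeature, int] | None = None):
        self.counts: Dict[PathFeature, int] = {
            k: v for k, v in (counts or {}).items() if v != 0
        }

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DescriptorMultiset) and self.counts == other.counts

    def __len__(self) -> int:
        return len(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __getitem__(self, feature: PathFeature) -> int:
        return self.counts.get(feature, 0)

    def __iter__(self):
        return iter(self.counts.items())

    def __add__(self, other: "DescriptorMultiset") -> "DescriptorMultiset":
        c = Counter(self.counts)
        c.update(other.counts)
        return DescriptorMultiset(c)

    def __sub__(self, other: "DescriptorMultiset") -> "DescriptorMultiset":
        c = Counter(self.counts)
        c.subtract(other.counts)
        return DescriptorMultiset(c)

    def positive_part(self) -> "DescriptorMultiset":
        return DescriptorMultiset({k: v for k, v in self.counts.items() if v > 0})

    def negative_part(self) -> "DescriptorMultiset":
        """Positive counts of the features with negative sign."""
        return DescriptorMultiset({k: -v for k, v in self.counts.items() if v < 0})

    def contains(self, other: "DescriptorMultiset") -> bool:
        """Count-aware multiset containment: other <= self."""
        return all(self.counts.get(k, 0) >= v for k, v in other.counts.items())

    def restrict(self, kind: str) -> "DescriptorMultiset":
        return DescriptorMultiset(
            {k: v for k, v in self.counts.items() if k.kind == kind}
        )

    def to_json(self) -> str:
        return json.dumps(
            {str(k): v for k, v in sorted(self.counts.items())}, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "DescriptorMultiset":
        return cls({_feature_from_string(k): v for k, v in json.loads(text).items()})

    def __repr__(self) -> str:
        items = ", ".join(f"{k}: {v}" for k, v in sorted(self.counts.items()))
        return f"DescriptorMultiset({{{items}}})"


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES: {smiles!r}")
    return mol


def path_descriptor_multiset(mol: Chem.Mol, length: int) -> DescriptorMultiset:
    """All canonical heavy-atom simple paths of 2 or 3 atoms, with counts."""
    if length not in (2, 3):
        raise ValueError("path length must be 2 or 3")
    types = {
        a.GetIdx(): type_atom(mol, a.GetIdx())
        for a in mol.GetAtoms()
        if a.GetAtomicNum() > 1
    }
    counts: Counter = Counter()
    if length == 2:
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i not in types or j not in types:
                continue
            feat = PathFeature(
                "AP2", (types[i], types[j]), (_bond_token(bond),)
            ).canonical()
            counts[feat] += 1
    else:
        for atom in mol.GetAtoms():
            j = atom.GetIdx()
            if j not in types:
                continue
            nbrs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetIdx() in types]
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    i, k = nbrs[a], nbrs[b]
                    bi = _bond_token(mol.GetBondBetweenAtoms(i, j))
                    bk = _bond_token(mol.GetBondBetweenAtoms(j, k))
                    feat = PathFeature(
                        "AP3", (types[i], types[j], types[k]), (bi, bk)
                    ).canonical()
                    counts[feat] += 1
    return DescriptorMultiset(counts)


def molecule_descriptor(mol: Chem.Mol) -> DescriptorMultiset:
    """AP2 + AP3 multiset of a (possibly multi-component) molecule.

    Components contribute independently: there are no cross-component
    paths, so the descriptor is additive over disconnected fragments.
    """
    return path_descriptor_multiset(mol, 2) + path_descriptor_multiset(mol, 3)


# ---------------------------------------------------------------------------
# Whole-molecule fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BitFingerprint:
    scheme: str
    n_bits: int
    on_bits: frozenset

    def __post_init__(self) -> None:
        if self.on_bits and max(self.on_bits) >= self.n_bits:
            raise ValueError("bit index out of range")

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.n_bits, dtype=np.uint8)
        if self.on_bits:
            arr[sorted(self.on_bits)] = 1
        return arr


@dataclass(frozen=True)
class CountFingerprint:
    scheme: str
    counts: Mapping[int, int]


# A small functional-group SMARTS dictionary in the spirit of
# dictionary-based fingerprints: one bit per group.
_FG_SMARTS = [
    ("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    ("ester", "[CX3](=O)[OX2H0][#6]"),
    ("amide", "[NX3][CX3](=[OX1])[#6]"),
    ("carbamate", "[NX3][CX3](=[OX1])[OX2][#6]"),
    ("primary_amine", "[NX3;H2;!$(NC=O)]"),
    ("secondary_amine", "[NX3;H1;!$(NC=O)]([#6])[#6]"),
    ("tertiary_amine", "[NX3;H0;!$(NC=O);!$(N=O)]([#6])([#6])[#6]"),
    ("hydroxyl", "[OX2H]"),
    ("phenol", "[OX2H][c]"),
    ("aliphatic_alcohol", "[OX2H][CX4]"),
    ("ether", "[OD2]([#6])[#6]"),
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("nitro", "[NX3+](=O)[O-]"),
    ("nitrile", "[NX1]#[CX2]"),
    ("halide_F", "[F]"),
    ("halide_Cl", "[Cl]"),
    ("halide_Br", "[Br]"),
    ("halide_I", "[I]"),
    ("alkyl_halide", "[CX4][Br,Cl,I]"),
    ("aryl_halide", "c[Br,Cl,I]"),
    ("boronic_acid", "[BX3]([OX2H])[OX2H]"),
    ("boron", "[B]"),
    ("alkene", "[CX3]=[CX3]"),
    ("alkyne", "[CX2]#[CX2]"),
    ("aromatic_ring", "a1aaaaa1"),
    ("aromatic_N", "[nX2,nX3]"),
    ("thiol", "[SX2H]"),
    ("thioether", "[SX2]([#6])[#6]"),
    ("sulfonamide", "[SX4](=O)(=O)[NX3]"),
    ("sulfonyl", "[SX4](=O)(=O)"),
    ("tbutyl", "[CX4]([CH3])([CH3])[CH3]"),
    ("benzylic_CH2", "[CH2]([c])[!c;!H]"),
    ("methoxy", "[OX2][CH3]"),
    ("trifluoromethyl", "[CX4](F)(F)F"),
]
_FG_PATTERNS = [(name, Chem.MolFromSmarts(s)) for name, s in _FG_SMARTS]


def _fp_maccs(mol: Chem.Mol) -> frozenset:
    return frozenset(MACCSkeys.GenMACCSKeys(mol).GetOnBits())


def _fp_avalon(n_bits: int) -> Callable[[Chem.Mol], frozenset]:
    def calc(mol: Chem.Mol) -> frozenset:
        return frozenset(pyAvalonTools.GetAvalonFP(mol, nBits=n_bits).GetOnBits())

    return calc


def _fp_featmorgan(radius: int, n_bits: int) -> Callable[[Chem.Mol], frozenset]:
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius,
        fpSize=n_bits,
        atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
    )

    def calc(mol: Chem.Mol) -> frozenset:
        return frozenset(gen.GetFingerprint(mol).GetOnBits())

    return calc


def _fp_functional_groups(mol: Chem.Mol) -> frozenset:
    on = {
        i
        for i, (_, patt) in enumerate(_FG_PATTERNS)
        if patt is not None and mol.HasSubstructMatch(patt)
    }
    return frozenset(on)


# scheme id -> (n_bits, callable)
_SCHEMES: Dict[str, Tuple[int, Callable[[Chem.Mol], frozenset]]] = {
    "maccs": (167, _fp_maccs),
    "hashed1024": (1024, _fp_avalon(1024)),
    "hashed2048": (2048, _fp_avalon(2048)),
    "hashed4096": (4096, _fp_avalon(4096)),
    "featmorgan1024_r1": (1024, _fp_featmorgan(1, 1024)),
    "featmorgan1024_r2": (1024, _fp_featmorgan(2, 1024)),
    "featmorgan2048_r2": (2048, _fp_featmorgan(2, 2048)),
    "fg": (len(_FG_SMARTS), _fp_functional_groups),
}


def registered_schemes() -> Tuple[str, ...]:
    return tuple(sorted(_SCHEMES))


def binary_fingerprint(mol: Chem.Mol, scheme: str) -> BitFingerprint:
    try:
        n_bits, calc = _SCHEMES[scheme]
    except KeyError:
        raise ValueError(
            f"unknown scheme {scheme!r}; registered: {', '.join(registered_schemes())}"
        )
    return BitFingerprint(scheme=scheme, n_bits=n_bits, on_bits=calc(mol))


_COUNT_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


def count_fingerprint(mol: Chem.Mol, scheme: str = "morgan_count1024") -> CountFingerprint:
    if scheme != "morgan_count1024":
        raise ValueError(f"unknown count scheme {scheme!r}")
    counts = _COUNT_GEN.GetCountFingerprint(mol).GetNonzeroElements()
    return CountFingerprint(scheme=scheme, counts=dict(counts))


def count_distance(a: CountFingerprint, b: CountFingerprint) -> float:
    """Euclidean distance between count fingerprints over the key union."""
    if a.scheme != b.scheme:
        raise ValueError(f"scheme mismatch: {a.scheme} vs {b.scheme}")
    keys = set(a.counts) | set(b.counts)
    return float(
        np.sqrt(sum((a.counts.get(k, 0) - b.counts.get(k, 0)) ** 2 for k in keys))
    )
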