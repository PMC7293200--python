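"""Applying reaction vectors to molecules: bounded bond-edit search.

A reaction vector pins down which typed atom-pair features must disappear
from the starting material (negative part) and which must appear in the
products (positive part).  The generator searches over bounded
combinations of bond edits — deletions, formations and order changes —
on the combined starting material + reagent graph, and accepts exactly
those edit sets whose descriptor change reproduces the vector.

The search is pruned in two stages:

* move enumeration is restricted to bonds whose current AP2 feature
  occurs in the negative part, and to new bonds between atoms whose
  current type occurs in the negative part (isolated atoms such as
  ammonia are admitted by element);
* for every candidate edit set the AP2 part of the descriptor change is
  predicted symbolically (degrees and pi counts are updated without
  touching the molecule) and only AP2-exact candidates are built,
  sanitized and verified against the full AP2+AP3 identity.

The number of deletions (formations) is bounded by the total negative
(positive) AP2 count, and the combined edit count by ``max_edits``.
By-products are reconstructed implicitly: the identity is checked over
all fragments of the edited graph and only the fragment holding the
former starting-material core is reported as the product.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit import RDLogger

from .descriptors import (
    AtomType,
    DescriptorMultiset,
    PathFeature,
    molecule_descriptor,
    type_atom,
)
from .reactions import ReactionVector, is_applicable

__all__ = ["apply_edits", "apply_reaction_vector"]

RDLogger.DisableLog("rdApp.*")

_TOKEN_TO_BONDTYPE = {
    "1": Chem.BondType.SINGLE,
    "2": Chem.BondType.DOUBLE,
    "3": Chem.BondType.TRIPLE,
    "a": Chem.BondType.AROMATIC,
}
_PI = {"1": 0, "2": 1, "3": 2, "a": 1}


def apply_edits(
    mol: Chem.Mol,
    breaks: Sequence[Tuple[int, int]] = (),
    forms: Sequence[Tuple[int, int, str]] = (),
    reorders: Sequence[Tuple[int, int, str]] = (),
) -> Optional[Chem.Mol]:
    """Apply bond edits and re-sanitize; None if the result is not valid.

    Touched atoms have their formal charge, radical count and explicit
    hydrogen count reset so that RDKit refills implicit hydrogens to the
    default valence (the edit machinery models heavy atoms only).
    """
    rw = Chem.RWMol(mol)
    touched = set()
    for i, j in breaks:
        if rw.GetBondBetweenAtoms(i, j) is None:
            return None
        rw.RemoveBond(i, j)
        touched.update((i, j))
    for i, j, token in forms:
        if rw.GetBondBetweenAtoms(i, j) is not None:
            return None
        rw.AddBond(i, j, _TOKEN_TO_BONDTYPE[token])
        touched.update((i, j))
    for i, j, token in reorders:
        bond = rw.GetBondBetweenAtoms(i, j)
        if bond is None:
            return None
        bond.SetBondType(_TOKEN_TO_BONDTYPE[token])
        if token != "a":
            bond.SetIsAromatic(False)
        touched.update((i, j))
    for idx in touched:
        atom = rw.GetAtomWithIdx(idx)
        atom.SetFormalCharge(0)
        atom.SetNumRadicalElectrons(0)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
        if not atom.IsInRing():
            atom.SetIsAromatic(False)
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _canon_ap2(a: AtomType, b: AtomType, token: str) -> PathFeature:
    return PathFeature("AP2", (a, b), (token,)).canonical()


class _EditSearch:
    def __init__(self, combined: Chem.Mol, rv: ReactionVector, max_edits: int):
        self.mol = combined
        self.rv = rv
        self.max_edits = max_edits
        self.types: Dict[int, AtomType] = {
            a.GetIdx(): type_atom(combined, a.GetIdx())
            for a in combined.GetAtoms()
            if a.GetAtomicNum() > 1
        }
        self.bonds: List[Tuple[int, int, str]] = []
        for bond in combined.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in self.types and j in self.types:
                token = {
                    Chem.BondType.SINGLE: "1",
                    Chem.BondType.DOUBLE: "2",
                    Chem.BondType.TRIPLE: "3",
                    Chem.BondType.AROMATIC: "a",
                }[bond.GetBondType()]
                self.bonds.append((min(i, j), max(i, j), token))
        self.bonds.sort()

        neg_ap2 = rv.negative.restrict("AP2")
        pos_ap2 = rv.positive.restrict("AP2")
        self.target_ap2: Dict[PathFeature, int] = dict(
            (rv.positive.restrict("AP2") - neg_ap2).counts
        )
        self.max_breaks = min(max_edits, sum(neg_ap2.counts.values()))
        self.max_forms = min(max_edits, sum(pos_ap2.counts.values()))

        # an atom gaining a bond changes type and so loses every AP2
        # feature it participates in; its current type therefore occurs in
        # the negative AP2 part (isolated atoms, which have no AP2
        # features, are admitted by element below)
        neg_types = {t for f in neg_ap2.counts for t in f.atom_types}
        pos_elem_pairs = set()
        pos_orders: Dict[Tuple[str, str], set] = {}
        for f in pos_ap2.counts:
            e = tuple(sorted((f.atom_types[0].element, f.atom_types[1].element)))
            pos_elem_pairs.add(e)
            pos_orders.setdefault(e, set()).add(f.bond_orders[0])
        pos_elems = {e for pair in pos_elem_pairs for e in pair}

        # breakable / reorderable: non-aromatic bonds whose current AP2
        # feature is lost by the reaction
        self.breakable: List[Tuple[int, int]] = []
        self.reorderable: List[Tuple[int, int, str]] = []
        for i, j, token in self.bonds:
            if token == "a":
                continue
            feat = _canon_ap2(self.types[i], self.types[j], token)
            if feat in neg_ap2.counts:
                self.breakable.append((i, j))
                e = tuple(sorted((self.types[i].element, self.types[j].element)))
                for new in pos_orders.get(e, ()):  # order change candidates
                    if new != token and new != "a":
                        self.reorderable.append((i, j, new))

        # formable endpoints: atoms losing an AP2 feature, plus isolated
        # atoms of a gained element (e.g. ammonia as a reagent)
        endpoints = [
            idx
            for idx, t in self.types.items()
            if t in neg_types
            or (t.heavy_degree == 0 and t.element in pos_elems)
        ]
        bonded = {(i, j) for i, j, _ in self.bonds}
        self.formable: List[Tuple[int, int, str]] = []
        for a_pos in range(len(endpoints)):
            for b_pos in range(a_pos + 1, len(endpoints)):
                i, j = sorted((endpoints[a_pos], endpoints[b_pos]))
                if (i, j) in bonded:
                    continue
                e = tuple(sorted((self.types[i].element, self.types[j].element)))
                for order in pos_orders.get(e, ()):
                    if order != "a":
                        self.formable.append((i, j, order))
        self.formable.sort()

    def predicted_ap2_delta(
        self,
        breaks: Tuple[Tuple[int, int], ...],
        forms: Tuple[Tuple[int, int, str], ...],
        reorders: Tuple[Tuple[int, int, str], ...],
    ) -> Optional[Dict[PathFeature, int]]:
        deg: Dict[int, int] = Counter()
        pi: Dict[int, int] = Counter()
        removed = set()
        retoken: Dict[Tuple[int, int], str] = {}
        cur_token = {(i, j): t for i, j, t in self.bonds}
        for i, j in breaks:
            removed.add((i, j))
            deg[i] -= 1
            deg[j] -= 1
            contrib = _PI[cur_token[(i, j)]]
            pi[i] -= contrib
            pi[j] -= contrib
        for i, j, token in forms:
            deg[i] += 1
            deg[j] += 1
            pi[i] += _PI[token]
            pi[j] += _PI[token]
        for i, j, token in reorders:
            if (i, j) in removed:
                return None
            retoken[(i, j)] = token
            dpi = _PI[token] - _PI[cur_token[(i, j)]]
            pi[i] += dpi
            pi[j] += dpi
        affected = set(deg) | set(pi)

        def new_type(idx: int) -> Optional[AtomType]:
            t = self.types[idx]
            nd, np_ = t.heavy_degree + deg[idx], t.pi_count + pi[idx]
            if nd < 0 or np_ < 0:
                return None
            return AtomType(t.element, nd, np_)

        new_types: Dict[int, AtomType] = {}
        for idx in affected:
            nt = new_type(idx)
            if nt is None:
                return None
            new_types[idx] = nt

        delta: Counter = Counter()
        for i, j, token in self.bonds:
            if (i, j) in removed:
                delta[_canon_ap2(self.types[i], self.types[j], token)] -= 1
                continue
            changed = i in affected or j in affected or (i, j) in retoken
            if not changed:
                continue
            old = _canon_ap2(self.types[i], self.types[j], token)
            ti = new_types.get(i, self.types[i])
            tj = new_types.get(j, self.types[j])
            new = _canon_ap2(ti, tj, retoken.get((i, j), token))
            if old != new:
                delta[old] -= 1
                delta[new] += 1
        for i, j, token in forms:
            ti = new_types.get(i, self.types[i])
            tj = new_types.get(j, self.types[j])
            delta[_canon_ap2(ti, tj, token)] += 1
        return {k: v for k, v in delta.items() if v != 0}


def apply_reaction_vector(
    rv: ReactionVector,
    sm: Chem.Mol,
    reagent: Optional[Chem.Mol] = None,
    max_products: int = 8,
    max_edits: int = 4,
    max_combos: int = 50000,
) -> List[Chem.Mol]:
    """Generate product molecules by applying a reaction vector.

    Raises if the vector is not applicable (precondition); returns an
    empty list when applicability holds but no valid bond-edit set
    reproduces the descriptor change.  Products are deduplicated by
    canonical SMILES and returned in canonical-SMILES order.
    """
    if not is_applicable(rv, sm, reagent):
        raise ValueError("reaction vector is not applicable to this input")
    sm = Chem.Mol(sm)
    for atom in sm.GetAtoms():
        atom.SetAtomMapNum(0)
    if rv.is_identity:
        return [sm]
    combined = sm
    if reagent is not None:
        reagent = Chem.Mol(reagent)
        for atom in reagent.GetAtoms():
            atom.SetAtomMapNum(0)
        combined = Chem.CombineMols(sm, reagent)
    n_sm_atoms = sm.GetNumAtoms()
    base = molecule_descriptor(combined)
    target = rv.delta()

    search = _EditSearch(combined, rv, max_edits)
    products: Dict[str, Chem.Mol] = {}
    tried = 0

    # Enumerate edit sets in order of increasing total edit count, trying
    # form-light splits first (few bonds are breakable but many pairs are
    # formable), and stop at the first split that yields products: larger
    # or form-heavier edit sets reproducing the same descriptor change are
    # redundant decorations of the same transformation.
    splits = [
        (size, nf, nr, size - nf - nr)
        for size in range(1, max_edits + 1)
        for nf in range(0, min(size, search.max_forms) + 1)
        for nr in range(0, size - nf + 1)
        if 0 <= size - nf - nr <= search.max_breaks
    ]
    for _, nf, nr, nb in splits:
        for br in combinations(search.breakable, nb):
            broken = set(br)
            reorder_pool = [
                r for r in search.reorderable if (r[0], r[1]) not in broken
            ]
            for ro in combinations(reorder_pool, nr):
                if len({(i, j) for i, j, _ in ro}) != nr:
                    continue
                for fo in combinations(search.formable, nf):
                    if len({(i, j) for i, j, _ in fo}) != nf:
                        continue
                    tried += 1
                    if tried > max_combos:
                        return _finalise(products, max_products)
                    pred = search.predicted_ap2_delta(br, fo, ro)
                    if pred is None or pred != search.target_ap2:
                        continue
                    edited = apply_edits(combined, br, fo, ro)
                    if edited is None:
                        continue
                    try:
                        delta = molecule_descriptor(edited) - base
                    except ValueError:
                        continue
                    if delta != target:
                        continue
                    main = _main_fragment(edited, n_sm_atoms)
                    if main is None:
                        continue
                    smi = Chem.MolToSmiles(main)
                    products.setdefault(smi, main)
        if products:
            break
    return _finalise(products, max_products)


def _main_fragment(mol: Chem.Mol, n_sm_atoms: int) -> Optional[Chem.Mol]:
    """The fragment holding the former starting-material core."""
    frag_ids = Chem.GetMolFrags(mol)
    try:
        frag_mols = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    except Exception:
        return None
    best = None
    best_key = None
    for ids, frag in zip(frag_ids, frag_mols):
        n_sm = sum(1 for idx in ids if idx < n_sm_atoms)
        key = (n_sm, frag.GetNumAtoms())
        if best_key is None or key > best_key:
            best, best_key = frag, key
    if best is None or best_key[0] == 0:
        return None
    return best


def _finalise(products: Dict[str, Chem.Mol], max_products: int) -> List[Chem.Mol]:
    ordered = sorted(products)[:max_products]
    return [products[s] for s in ordered]
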