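"""Synthetic classified-reaction generator.

Real recommender training sets are built from patent reaction corpora;
this module emulates their statistical structure on a small, fully
self-contained scale so that every stage of the pipeline — vector
computation, dataset pivoting, recommender training, filtered enumeration
and retrosynthetic reassembly — can be exercised without any external
download.

The generator is template-driven: each :class:`ReactionTemplate` owns a
reaction-class label, a pool of starting materials, an optional reagent
pool and a graph-edit rule.  Reactions are born mapped and balanced
(by-products are recorded), and map numbers are kept only for atoms that
end up in the main product, mirroring corpus data in which by-products go
unrecorded.  Design features deliberately emulated:

* skewed class frequencies (C-N bond formation, functional conversion
  and deprotection dominate);
* the same starting material recurring under several classes (acids
  feed both amide and ester condensations, amines feed alkylation and
  Boc protection), so pivoting produces genuine multi-label entries;
* a competing-functionality family: molecules carrying both an NH and an
  OH group appear only under Functional Conversion and Protection,
  never under coupling/condensation classes;
* a three-fragment RENATE target whose joins are covered by the fixture
  reaction vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .descriptors import mol_from_smiles
from .generator import apply_edits
from .labels import ReactionClassLabel, parse_label
from .reactions import Reaction, ReactionVector, compute_reaction_vector

__all__ = [
    "ReactionTemplate",
    "FixtureSpec",
    "RenateCase",
    "TEMPLATES",
    "DEFAULT_CLASS_WEIGHTS",
    "build_reaction",
    "generate_classified_reactions",
    "generate_renate_case",
    "ambiguous_reaction",
]


def _graft(core: str, rgroup: str) -> str:
    """Join a ``[*:1]``-marked core with a ``[*:1]``-marked substituent."""
    combo = Chem.CombineMols(mol_from_smiles(core), mol_from_smiles(rgroup))
    out = Chem.molzip(combo)
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


_R_ARYL = [
    "[*:1]c1ccccc1",
    "[*:1]c1ccc(C)cc1",
    "[*:1]c1ccc(F)cc1",
    "[*:1]c1ccc(Cl)cc1",
    "[*:1]c1ccc(OC)cc1",
    "[*:1]c1ccc(CC)cc1",
    "[*:1]c1cccc(C)c1",
    "[*:1]c1ccc2ccccc2c1",
]

_ACIDS = tuple(
    _graft(core, r) for core in ("[*:1]C(=O)O", "[*:1]CC(=O)O") for r in _R_ARYL
)
_AMINES = tuple(
    _graft(core, r) for core in ("[*:1]CN", "[*:1]CCN") for r in _R_ARYL
)
_ALCOHOLS = tuple(
    _graft(core, r) for core in ("[*:1]CO", "[*:1]CCO") for r in _R_ARYL[:6]
)
_ARYL_BROMIDES = tuple(_graft("[*:1]Cc1ccc(Br)cc1", r) for r in _R_ARYL)
_CARBAMATES = tuple(
    _graft("[*:1]CCNC(=O)OC(C)(C)C", r) for r in _R_ARYL
)
_NITROARENES = tuple(
    _graft("O=[N+]([O-])c1ccc([*:1])cc1", r)
    for r in ("[*:1]C", "[*:1]CC", "[*:1]OC", "[*:1]CCC", "[*:1]C(C)C") + tuple(_R_ARYL[:5])
)
_ALKENES = tuple(
    _graft(core, r) for core in ("[*:1]C=C", "[*:1]CC=C") for r in _R_ARYL[:5]
)
# competing-functionality family: an NH2, an OH and one alkene each
_AMINO_ALCOHOL_ALKENES = (
    "NC(CO)CCC=C",
    "NC(CO)CCCC=C",
    "NC(CO)CCCCC=C",
    "NC(CO)CCC=CC",
    "NCC(O)CCC=C",
    "NCC(O)CCCC=C",
    "NCC(O)CCCCC=C",
    "NC(CO)Cc1ccc(C=C)cc1",
    "NCC(O)Cc1ccc(C=C)cc1",
    "NC(CO)C(C)CC=C",
)

_AMINE_REAGENTS = ("NC", "NCC", "NCCC", "CNC")
_ALCOHOL_REAGENTS = ("OC", "OCC", "OCCC")
_ALKYL_BROMIDES = ("BrC", "BrCC", "BrCCC")
_BORONIC_ACIDS = (
    "OB(O)c1ccccc1",
    "OB(O)c1ccc(C)cc1",
    "OB(O)c1ccc(F)cc1",
    "OB(O)c1ccc(OC)cc1",
)
_BOC_ANHYDRIDE = ("CC(C)(C)OC(=O)OC(=O)OC(C)(C)C",)

Edits = Tuple[
    Tuple[Tuple[int, int], ...],       # breaks
    Tuple[Tuple[int, int, str], ...],  # forms
    Tuple[Tuple[int, int, str], ...],  # reorders
]


@dataclass(frozen=True)
class ReactionTemplate:
    """A labelled transformation rule over starting-material/reagent pools."""

    name: str
    label: ReactionClassLabel
    sm_pool: Tuple[str, ...]
    reagent_pool: Optional[Tuple[str, ...]]
    sm_smarts: str
    rg_smarts: Optional[str]
    edit: Callable[[Tuple[int, ...], Tuple[int, ...]], Edits]


def _t(label: str) -> ReactionClassLabel:
    return parse_label(label)


def _e_amide(sm: Tuple[int, ...], rg: Tuple[int, ...]) -> Edits:
    c, _, oh = sm
    n = rg[0]
    return ((( c, oh),), ((c, n, "1"),), ())


def _e_ester(sm: Tuple[int, ...], rg: Tuple[int, ...]) -> Edits:
    c, _, oh = sm
    o = rg[0]
    return (((c, oh),), ((c, o, "1"),), ())


def _e_n_alkylation(sm: Tuple[int, ...], rg: Tuple[int, ...]) -> Edits:
    n = sm[0]
    c, br = rg
    return (((c, br),), ((n, c, "1"),), ())


def _e_boc_protection(sm: Tuple[int, ...], rg: Tuple[int, ...]) -> Edits:
    n = sm[0]
    c1, _odbl, _oe, _ct, _m1, _m2, _m3, ob = rg
    return (((c1, ob),), ((n, c1, "1"),), ())


def _e_boc_deprotection(sm: Tuple[int, ...], rg: Tuple[int, ...]) -> Edits:
    n, c = sm[0], sm[1]
    return (((n, c),), (), ())


def _e_suzuki(sm: Tuple[int, ...], rg: Tuple[int, ...]) -> Edits:
    c_s, br = sm
    c_r, b = rg[0], rg[1]
    return (((c_s, br), (c_r, b)), ((c_s, c_r, "1"),), ())


def _e_nitro_reduction(sm: Tuple[int, ...], rg: Tuple[int, ...]) -> Edits:
    n, o1, o2 = sm
    return (((n, o1), (n, o2)), (), ())


def _e_hydrogenation(sm: Tuple[int, ...], rg: Tuple[int, ...]) -> Edits:
    c1, c2 = sm
    return ((), (), ((min(c1, c2), max(c1, c2), "1"),))


def _e_williamson(sm: Tuple[int, ...], rg: Tuple[int, ...]) -> Edits:
    o = sm[0]
    c, br = rg
    return (((c, br),), ((o, c, "1"),), ())


TEMPLATES: Dict[str, ReactionTemplate] = {
    t.name: t
    for t in (
        ReactionTemplate(
            "amide_coupling",
            _t("C-N Bond Formation (Condensation) (Amide)"),
            _ACIDS, _AMINE_REAGENTS,
            "[CX3](=[OX1])[OX2H1]", "[NX3;H2,H1;!$(NC=O)]",
            _e_amide,
        ),
        ReactionTemplate(
            "n_alkylation",
            _t("C-N Bond Formation (Alkylation) (Bromo)"),
            _AMINES, _ALKYL_BROMIDES,
            "[NX3;H2;!$(NC=O)]", "[CX4][Br]",
            _e_n_alkylation,
        ),
        ReactionTemplate(
            "boc_deprotection",
            _t("Deprotection (Boc) (Amine)"),
            _CARBAMATES, None,
            "[NX3;H1][CX3](=[OX1])[OX2][CX4]", None,
            _e_boc_deprotection,
        ),
        ReactionTemplate(
            "nitro_reduction",
            _t("Functional Conversion (Reduction) (Nitro to amino)"),
            _NITROARENES, None,
            "[NX3+](=[OX1])[OX1-]", None,
            _e_nitro_reduction,
        ),
        ReactionTemplate(
            "hydrogenation",
            _t("Functional Conversion (Hydrogenation) (Alkene to alkane)"),
            _ALKENES + _AMINO_ALCOHOL_ALKENES, None,
            "[CX3;!$(C=O)]=[CX3]", None,
            _e_hydrogenation,
        ),
        ReactionTemplate(
            "boc_protection",
            _t("Protection (Boc) (Amine)"),
            _AMINES + _AMINO_ALCOHOL_ALKENES, _BOC_ANHYDRIDE,
            "[NX3;H2;!$(NC=O)]",
            "[CX3](=[OX1])([OX2][C]([CH3])([CH3])[CH3])[OX2]",
            _e_boc_protection,
        ),
        ReactionTemplate(
            "suzuki_coupling",
            _t("C-C Bond Formation (Coupling) (Suzuki) (Bromo)"),
            _ARYL_BROMIDES, _BORONIC_ACIDS,
            "[c][Br]", "[c][BX3]([OX2H])[OX2H]",
            _e_suzuki,
        ),
        ReactionTemplate(
            "ester_formation",
            _t("C-O Bond Formation (Condensation) (Ester)"),
            _ACIDS, _ALCOHOL_REAGENTS,
            "[CX3](=[OX1])[OX2H1]", "[OX2H1]",
            _e_ester,
        ),
        ReactionTemplate(
            "williamson_ether",
            _t("C-O Bond Formation (Alkylation) (Williamson)"),
            _ALCOHOLS, _ALKYL_BROMIDES,
            "[OX2H1]", "[CX4][Br]",
            _e_williamson,
        ),
    )
}

# Skewed class frequencies: C-N bond formation dominates, followed by
# functional conversions and deprotections.
DEFAULT_CLASS_WEIGHTS: Dict[str, float] = {
    "amide_coupling": 0.20,
    "n_alkylation": 0.15,
    "boc_deprotection": 0.13,
    "nitro_reduction": 0.10,
    "hydrogenation": 0.10,
    "boc_protection": 0.08,
    "suzuki_coupling": 0.08,
    "ester_formation": 0.08,
    "williamson_ether": 0.08,
}


@dataclass(frozen=True)
class FixtureSpec:
    n_reactions: int
    class_weights: Optional[Dict[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")
        if self.class_weights is not None:
            if any(w <= 0 for w in self.class_weights.values()):
                raise ValueError("class weights must be positive")
            unknown = set(self.class_weights) - set(TEMPLATES)
            if unknown:
                raise ValueError(f"weights for unregistered templates: {unknown}")


def build_reaction(
    template: ReactionTemplate, sm_smiles: str, reagent_smiles: Optional[str] = None
) -> Reaction:
    """Instantiate a template on concrete structures.

    The returned reaction is carbon-balanced with all by-products
    recorded; atom map numbers are assigned to every reactant atom and
    then kept only for atoms that end up in the main product.
    """
    sm = mol_from_smiles(sm_smiles)
    reagent = mol_from_smiles(reagent_smiles) if reagent_smiles else None
    if reagent is None and template.reagent_pool is not None:
        raise ValueError(f"template {template.name} requires a reagent")
    for i, atom in enumerate(sm.GetAtoms()):
        atom.SetAtomMapNum(i + 1)
    offset = sm.GetNumAtoms()
    combined = sm
    if reagent is not None:
        for i, atom in enumerate(reagent.GetAtoms()):
            atom.SetAtomMapNum(offset + i + 1)
        combined = Chem.CombineMols(sm, reagent)

    sm_match = sm.GetSubstructMatch(Chem.MolFromSmarts(template.sm_smarts))
    if not sm_match:
        raise ValueError(
            f"{template.name}: starting material {sm_smiles!r} lacks the reaction site"
        )
    rg_match: Tuple[int, ...] = ()
    if template.rg_smarts is not None:
        raw = reagent.GetSubstructMatch(Chem.MolFromSmarts(template.rg_smarts))
        if not raw:
            raise ValueError(
                f"{template.name}: reagent {reagent_smiles!r} lacks the reaction site"
            )
        rg_match = tuple(offset + idx for idx in raw)

    breaks, forms, reorders = template.edit(sm_match, rg_match)
    edited = apply_edits(combined, breaks, forms, reorders)
    if edited is None:
        raise ValueError(f"{template.name}: edit failed on {sm_smiles!r}")

    frag_ids = Chem.GetMolFrags(edited)
    frag_mols = Chem.GetMolFrags(edited, asMols=True, sanitizeFrags=True)
    ranked = sorted(
        zip(frag_ids, frag_mols),
        key=lambda p: (sum(1 for i in p[0] if i < offset), p[1].GetNumAtoms()),
        reverse=True,
    )
    main = ranked[0][1]
    byproducts = [m for _, m in ranked[1:]]
    main_maps = {a.GetAtomMapNum() for a in main.GetAtoms() if a.GetAtomMapNum()}
    for frag in byproducts:
        for atom in frag.GetAtoms():
            atom.SetAtomMapNum(0)
    reactants = [sm] + ([reagent] if reagent is not None else [])
    for mol in reactants:
        for atom in mol.GetAtoms():
            if atom.GetAtomMapNum() not in main_maps:
                atom.SetAtomMapNum(0)
    return Reaction(
        reactants=reactants, products=[main] + byproducts, label=template.label
    )


def generate_classified_reactions(spec: FixtureSpec) -> List[Reaction]:
    """Sample labelled, balanced, mapped reactions under the class skew."""
    weights = dict(spec.class_weights or DEFAULT_CLASS_WEIGHTS)
    names = sorted(weights)
    p = np.array([weights[n] for n in names], dtype=float)
    p /= p.sum()
    rng = np.random.default_rng(spec.seed)
    out: List[Reaction] = []
    for _ in range(spec.n_reactions):
        template = TEMPLATES[names[rng.choice(len(names), p=p)]]
        sm = template.sm_pool[rng.integers(len(template.sm_pool))]
        reagent = None
        if template.reagent_pool is not None:
            reagent = template.reagent_pool[rng.integers(len(template.reagent_pool))]
        out.append(build_reaction(template, sm, reagent))
    return out


def ambiguous_reaction() -> Reaction:
    """Two reactants with the same mapped-atom count (discard case)."""
    rxn = build_reaction(TEMPLATES["amide_coupling"], _ACIDS[0], "NCC")
    # remap so both reactants tie
    n_keep = 3
    for mol in rxn.reactants:
        mapped = [a for a in mol.GetAtoms() if a.GetAtomMapNum()]
        for a in mapped[n_keep:]:
            a.SetAtomMapNum(0)
    return rxn


@dataclass(frozen=True)
class RenateCase:
    """A decomposable target, a reagent pool and covering reaction vectors."""

    target: str
    pool: Tuple[str, ...]
    vectors: Tuple[ReactionVector, ...]


def generate_renate_case(seed: int = 0) -> RenateCase:
    """A 3-fragment target with its joins covered by fixture vectors.

    The target is an N-arylethyl benzamide bearing a benzyl aryl ether;
    its BRICS cleavages (amide C-N, benzylic ether C-O) meet the
    five-heavy-atom minimum.  The pool holds the three exact building
    blocks plus decoys drawn from the template families; the vector set
    covers the two joins (amide condensation, Williamson etherification)
    and includes labelled decoy vectors.  The two join vectors are left
    unlabelled, emulating partially classified vector collections.
    """
    target = "O=C(NCCc1ccc(OCc2ccccc2)cc1)C1CCCC1"
    building_blocks = (
        "OC(=O)C1CCCC1",          # cyclopentanecarboxylic acid
        "NCCc1ccc(O)cc1",         # tyramine
        "BrCc1ccccc1",            # benzyl bromide
    )
    rng = np.random.default_rng(seed)
    decoys: List[str] = []
    decoys += list(_ACIDS[:10])
    decoys += list(_AMINES[:10])
    decoys += list(_ALCOHOLS[:8])
    decoys += list(_ALKENES[:6])
    decoys += list(_NITROARENES[:6])
    decoys += list(_ARYL_BROMIDES[:4])
    decoys += list(_CARBAMATES[:4])
    decoys += list(_ALKYL_BROMIDES) + ["OB(O)c1ccccc1"]
    decoys = [d for d in dict.fromkeys(decoys) if d not in building_blocks]
    pool = list(building_blocks) + decoys
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]

    def vector(template_name: str, sm: str, rg: Optional[str], vid: str,
               labelled: bool) -> ReactionVector:
        rxn = build_reaction(TEMPLATES[template_name], sm, rg)
        rv = compute_reaction_vector(rxn, id=vid)
        if not labelled:
            rv.source_label = None
        return rv

    vectors = (
        # join vectors, environments matched to the target's fragments
        vector("amide_coupling", "OC(=O)C1CCCC1", "NCCc1ccccc1",
               "rv-amide", labelled=False),
        vector("williamson_ether", "Cc1ccc(O)cc1", "BrCc1ccccc1",
               "rv-ether", labelled=False),
        # labelled decoys
        vector("n_alkylation", _AMINES[0], "BrCC", "rv-alkylation", True),
        vector("boc_deprotection", _CARBAMATES[0], None, "rv-deprotection", True),
        vector("nitro_reduction", _NITROARENES[0], None, "rv-nitro", True),
        vector("hydrogenation", _ALKENES[0], None, "rv-hydrogenation", True),
        vector("suzuki_coupling", _ARYL_BROMIDES[0], _BORONIC_ACIDS[0],
               "rv-suzuki", True),
        vector("ester_formation", _ACIDS[0], "OCC", "rv-ester", True),
        vector("boc_protection", _AMINES[1], _BOC_ANHYDRIDE[0], "rv-protection", True),
    )
    return RenateCase(target=target, pool=tuple(pool), vectors=vectors)
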