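"""De novo enumeration: recommender-filtered design and RENATE.

Single-step design scans a set of reaction vectors against each starting
material (alone, and combined with each reagent), optionally filtering
the vectors to the classes recommended for that starting material, and
collects every generated product.  An empty recommendation disables the
filter — the molecule is simply outside the recommender's domain.

RENATE (retrosynthetic design with reaction vectors) rediscovers or
varies a reference molecule: the reference is cleaved into fragments
(BRICS bonds, minimum fragment size enforced), analogs of each fragment
are retrieved from a reagent pool by count-fingerprint Euclidean
distance, and the analog sets are reassembled combinatorially through
applicable reaction vectors, keeping a beam of the products closest to
the reference between iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

from .dataset import canonical_id
from .descriptors import (
    CountFingerprint,
    DescriptorMultiset,
    binary_fingerprint,
    count_distance,
    count_fingerprint,
    molecule_descriptor,
)
from .generator import apply_reaction_vector
from .labels import ReactionClassLabel, matches_at_level, truncate_label
from .reactions import ReactionVector, is_applicable
from .recommender import Recommendation, RecommenderModel, predict

logger = logging.getLogger(__name__)

__all__ = [
    "ProductRecord",
    "LibraryStats",
    "RenateConfig",
    "EnumerationLimits",
    "filter_reaction_vectors",
    "single_step_enumerate",
    "library_stats",
    "fragment_reference",
    "retrieve_analogs",
    "renate_run",
]


@dataclass
class ProductRecord:
    product: Chem.Mol
    canonical_id: str
    sm_id: str
    reagent_id: Optional[str]
    rv_id: str
    rv_label: Optional[ReactionClassLabel]
    similarity: Optional[float] = None  # distance to a reference; lower is closer


@dataclass
class LibraryStats:
    n_unique: int
    overlap_pct: Optional[float]
    class_composition: Dict[str, float]
    external_scores: Dict[str, float]


@dataclass(frozen=True)
class RenateConfig:
    min_fragment_atoms: int = 5
    analogs_per_fragment: int = 1000
    beam_width: int = 25
    similarity_scheme: str = "morgan_count1024"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.min_fragment_atoms, self.analogs_per_fragment, self.beam_width) < 1:
            raise ValueError("RENATE config values must be positive")


@dataclass(frozen=True)
class EnumerationLimits:
    max_products_per_application: int = 8
    max_edits: int = 4


def filter_reaction_vectors(
    rvs: Sequence[ReactionVector],
    rec: Optional[Recommendation],
    level: int,
    drop_unlabelled: bool = False,
) -> List[ReactionVector]:
    """Keep the vectors whose class is recommended.

    An empty (or absent) recommendation applies no filter.  Unlabelled
    vectors are retained by default: reaction-vector collections are
    typically only partially classified, and dropping them would silently
    cripple a run.
    """
    if rec is None or rec.is_empty:
        return list(rvs)
    out = []
    for rv in rvs:
        if rv.source_label is None:
            if not drop_unlabelled:
                out.append(rv)
            continue
        if any(matches_at_level(rv.source_label, r, level) for r in rec.labels):
            out.append(rv)
    return out


def _strip_maps(mol: Chem.Mol) -> Chem.Mol:
    clean = Chem.Mol(mol)
    for atom in clean.GetAtoms():
        atom.SetAtomMapNum(0)
    return clean


class _DescriptorCache:
    def __init__(self) -> None:
        self._store: Dict[str, DescriptorMultiset] = {}

    def get(self, mol: Chem.Mol, key: str) -> DescriptorMultiset:
        if key not in self._store:
            self._store[key] = molecule_descriptor(mol)
        return self._store[key]


def single_step_enumerate(
    sms: Sequence[Chem.Mol],
    reagents: Sequence[Chem.Mol],
    rvs: Sequence[ReactionVector],
    model: Optional[RecommenderModel] = None,
    level: int = 3,
    limits: EnumerationLimits = EnumerationLimits(),
    drop_unlabelled: bool = False,
) -> List[ProductRecord]:
    """One design iteration over all starting materials.

    For each starting material the vectors are (optionally) filtered by
    its recommendation, tested for applicability against the molecule
    alone and against the molecule plus each reagent, and applied.
    Per-molecule failures are logged and skipped.
    """
    cache = _DescriptorCache()
    records: List[ProductRecord] = []
    for sm in sms:
        sm_id = canonical_id(sm)
        try:
            rec = None
            if model is not None:
                rec = predict(model, binary_fingerprint(_strip_maps(sm), model.scheme))
            applicable_rvs = filter_reaction_vectors(rvs, rec, level, drop_unlabelled)
            sm_desc = cache.get(sm, sm_id)
            for rv in applicable_rvs:
                if is_applicable(rv, sm, sm_descriptor=sm_desc):
                    _apply_and_record(
                        records, rv, sm, sm_id, None, None, None, limits
                    )
                    continue
                for reagent in reagents:
                    rg_id = canonical_id(reagent)
                    if is_applicable(
                        rv,
                        sm,
                        reagent,
                        sm_descriptor=sm_desc,
                        reagent_descriptor=cache.get(reagent, rg_id),
                    ):
                        _apply_and_record(
                            records, rv, sm, sm_id, reagent, rg_id, None, limits
                        )
        except Exception:
            logger.exception("enumeration failed for %s; skipping", sm_id)
    return records


def _apply_and_record(
    records: List[ProductRecord],
    rv: ReactionVector,
    sm: Chem.Mol,
    sm_id: str,
    reagent: Optional[Chem.Mol],
    reagent_id: Optional[str],
    ref_cfp: Optional[CountFingerprint],
    limits: EnumerationLimits,
) -> None:
    products = apply_reaction_vector(
        rv,
        sm,
        reagent,
        max_products=limits.max_products_per_application,
        max_edits=limits.max_edits,
    )
    for product in products:
        similarity = None
        if ref_cfp is not None:
            similarity = count_distance(count_fingerprint(product), ref_cfp)
        records.append(
            ProductRecord(
                product=product,
                canonical_id=canonical_id(product),
                sm_id=sm_id,
                reagent_id=reagent_id,
                rv_id=rv.id,
                rv_label=rv.source_label,
                similarity=similarity,
            )
        )


def library_stats(
    records: Sequence[ProductRecord],
    reference_ids: Optional[Set[str]] = None,
    scorers: Optional[Dict[str, Callable[[Chem.Mol], float]]] = None,
) -> LibraryStats:
    """Deduplicate and summarise a product library.

    Overlap is the percentage of unique library members whose canonical
    id occurs in the reference id set.  Class composition is computed
    over the level-1 class of the generating vector (unlabelled vectors
    pool under "Unclassified").  External scorers (e.g. synthetic
    accessibility estimates) are applied per unique product and averaged;
    a failing scorer is omitted.
    """
    unique: Dict[str, ProductRecord] = {}
    for r in records:
        unique.setdefault(r.canonical_id, r)
    n_unique = len(unique)
    overlap = None
    if reference_ids is not None:
        overlap = (
            100.0 * sum(1 for cid in unique if cid in reference_ids) / n_unique
            if n_unique
            else 0.0
        )
    comp: Dict[str, float] = {}
    for r in records:
        key = r.rv_label.levels[0] if r.rv_label is not None else "Unclassified"
        comp[key] = comp.get(key, 0) + 1
    total = sum(comp.values())
    comp = {k: v / total for k, v in comp.items()} if total else {}
    scores: Dict[str, float] = {}
    for name, fn in (scorers or {}).items():
        try:
            vals = [fn(r.product) for r in unique.values()]
            scores[name] = float(np.mean(vals)) if vals else 0.0
        except Exception:
            logger.exception("scorer %s failed; omitted", name)
    return LibraryStats(
        n_unique=n_unique,
        overlap_pct=overlap,
        class_composition=comp,
        external_scores=scores,
    )


def _heavy_atoms(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def fragment_reference(ref: Chem.Mol, cfg: RenateConfig) -> List[Chem.Mol]:
    """Cleave a reference at BRICS bonds, enforcing a minimum fragment size.

    Candidate bonds are considered in deterministic order and cut only
    when both resulting pieces keep at least ``min_fragment_atoms`` heavy
    atoms.  Fragments carry dummy atoms at the attachment points and are
    ranked by (number of attachment points, heavy atoms) descending; the
    first fragment is the scaffold.  A molecule with no cleavable bond is
    returned whole.
    """
    Chem.SanitizeMol(ref)
    candidate_pairs = sorted(
        (min(i, j), max(i, j)) for (i, j), _ in BRICS.FindBRICSBonds(ref)
    )
    n = ref.GetNumAtoms()
    adjacency = {a.GetIdx(): set() for a in ref.GetAtoms()}
    for bond in ref.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i].add(j)
        adjacency[j].add(i)

    def component(start: int, cut: Set[Tuple[int, int]]) -> Set[int]:
        seen = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb in adjacency[cur]:
                edge = (min(cur, nb), max(cur, nb))
                if edge in cut or nb in seen:
                    continue
                seen.add(nb)
                stack.append(nb)
        return seen

    heavy = {a.GetIdx() for a in ref.GetAtoms() if a.GetAtomicNum() > 1}
    cuts: Set[Tuple[int, int]] = set()
    for pair in candidate_pairs:
        trial = cuts | {pair}
        side_i = component(pair[0], trial)
        side_j = component(pair[1], trial)
        if len(side_i & heavy) >= cfg.min_fragment_atoms and len(
            side_j & heavy
        ) >= cfg.min_fragment_atoms:
            cuts.add(pair)
    if not cuts:
        return [Chem.Mol(ref)]
    bond_indices = [
        ref.GetBondBetweenAtoms(i, j).GetIdx() for i, j in sorted(cuts)
    ]
    cut_mol = Chem.FragmentOnBonds(ref, bond_indices, addDummies=True)
    frags = list(Chem.GetMolFrags(cut_mol, asMols=True, sanitizeFrags=True))
    frags.sort(
        key=lambda m: (
            -sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 0),
            -_heavy_atoms(m),
            Chem.MolToSmiles(m),
        )
    )
    return frags


def strip_attachment_points(fragment: Chem.Mol) -> Chem.Mol:
    """Replace attachment dummies by hydrogens."""
    rw = Chem.RWMol(fragment)
    for idx in sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def retrieve_analogs(
    fragment: Chem.Mol,
    pool: Sequence[Chem.Mol],
    k: int,
    scheme: str = "morgan_count1024",
) -> List[Chem.Mol]:
    """k nearest pool members to the fragment by count-fingerprint distance.

    The fragment itself (attachment points stripped) joins the candidate
    set, so an exact match always ranks first at distance zero.
    """
    if not pool:
        raise ValueError("empty reagent pool")
    query = strip_attachment_points(fragment)
    query_fp = count_fingerprint(query, scheme)
    candidates: Dict[str, Tuple[float, str, Chem.Mol]] = {}
    for mol in list(pool) + [query]:
        cid = canonical_id(mol)
        if cid in candidates:
            continue
        dist = count_distance(count_fingerprint(mol, scheme), query_fp)
        candidates[cid] = (dist, Chem.MolToSmiles(mol), mol)
    ranked = sorted(candidates.values())
    if k > len(ranked):
        logger.info("k=%d exceeds candidate pool (%d); returning all", k, len(ranked))
    return [mol for _, _, mol in ranked[:k]]


def renate_run(
    ref: Chem.Mol,
    pool: Sequence[Chem.Mol],
    rvs: Sequence[ReactionVector],
    model: Optional[RecommenderModel] = None,
    cfg: RenateConfig = RenateConfig(),
    level: int = 3,
    limits: EnumerationLimits = EnumerationLimits(),
    drop_unlabelled: bool = False,
) -> Tuple[List[ProductRecord], bool]:
    """Fragment, retrieve, reassemble; report whether the reference reappears.

    Iteration *i* combines the current starting set (initially the
    scaffold-fragment analogs) with the analogs of the next ranked
    fragment through every applicable (optionally recommender-filtered)
    reaction vector; products are scored by count-fingerprint distance to
    the reference and the ``beam_width`` closest survive as the next
    starting set.  Rediscovery means the reference's canonical id occurs
    among the generated products.
    """
    ref = Chem.Mol(ref)
    Chem.SanitizeMol(ref)
    target_id = canonical_id(ref)
    ref_cfp = count_fingerprint(ref, cfg.similarity_scheme)
    fragments = fragment_reference(ref, cfg)
    analog_sets = [
        retrieve_analogs(f, pool, cfg.analogs_per_fragment, cfg.similarity_scheme)
        for f in fragments
    ]
    if len(analog_sets) == 1:
        found = any(canonical_id(m) == target_id for m in analog_sets[0])
        return [], found
    cache = _DescriptorCache()
    current = analog_sets[0]
    all_records: List[ProductRecord] = []
    for nxt in analog_sets[1:]:
        step_records: List[ProductRecord] = []
        for a in current:
            a_id = canonical_id(a)
            rec = None
            if model is not None:
                rec = predict(model, binary_fingerprint(_strip_maps(a), model.scheme))
            step_rvs = filter_reaction_vectors(rvs, rec, level, drop_unlabelled)
            a_desc = cache.get(a, a_id)
            for b in nxt:
                b_id = canonical_id(b)
                if a_id == b_id:
                    continue
                b_desc = cache.get(b, b_id)
                for rv in step_rvs:
                    for sm, sm_id, rg, rg_id, sm_d, rg_d in (
                        (a, a_id, b, b_id, a_desc, b_desc),
                        (b, b_id, a, a_id, b_desc, a_desc),
                    ):
                        if not is_applicable(
                            rv, sm, rg, sm_descriptor=sm_d, reagent_descriptor=rg_d
                        ):
                            continue
                        try:
                            _apply_and_record(
                                step_records, rv, sm, sm_id, rg, rg_id, ref_cfp, limits
                            )
                        except Exception:
                            logger.exception(
                                "application of %s failed on %s; skipping", rv.id, sm_id
                            )
        # deduplicate per step, keep the beam of closest products
        by_id: Dict[str, ProductRecord] = {}
        for r in step_records:
            prev = by_id.get(r.canonical_id)
            if prev is None or (r.similarity, r.sm_id) < (prev.similarity, prev.sm_id):
                by_id[r.canonical_id] = r
        all_records.extend(step_records)
        if not by_id:
            logger.info("empty intermediate product set; stopping early")
            return all_records, False
        beam = sorted(by_id.values(), key=lambda r: (r.similarity, r.canonical_id))
        current = [r.product for r in beam[: cfg.beam_width]]
    rediscovered = any(r.canonical_id == target_id for r in all_records)
    return all_records, rediscovered
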