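"""Recommender-filtered enumeration, library statistics and RENATE."""

import numpy as np
import pytest
from rdkit import Chem

from rvdesign.dataset import canonical_id
from rvdesign.descriptors import count_distance, count_fingerprint, mol_from_smiles
from rvdesign.design import (
    EnumerationLimits,
    ProductRecord,
    RenateConfig,
    filter_reaction_vectors,
    fragment_reference,
    library_stats,
    renate_run,
    retrieve_analogs,
    single_step_enumerate,
    strip_attachment_points,
)
from rvdesign.fixtures import TEMPLATES, build_reaction, generate_renate_case
from rvdesign.labels import parse_label
from rvdesign.reactions import compute_reaction_vector
from rvdesign.recommender import Recommendation


@pytest.fixture(scope="module")
def labelled_vectors():
    specs = [
        ("amide_coupling", TEMPLATES["amide_coupling"].sm_pool[0], "NCC"),
        ("ester_formation", TEMPLATES["ester_formation"].sm_pool[0], "OCC"),
        ("suzuki_coupling", TEMPLATES["suzuki_coupling"].sm_pool[0],
         TEMPLATES["suzuki_coupling"].reagent_pool[0]),
        ("nitro_reduction", TEMPLATES["nitro_reduction"].sm_pool[0], None),
    ]
    out = []
    for i, (name, sm, rg) in enumerate(specs):
        rxn = build_reaction(TEMPLATES[name], sm, rg)
        out.append(compute_reaction_vector(rxn, id=f"rv{i}"))
    return out


class TestFilter:
    def test_empty_recommendation_is_no_filter(self, labelled_vectors):
        rec = Recommendation(labels=frozenset())
        assert filter_reaction_vectors(labelled_vectors, rec, 3) == labelled_vectors
        assert filter_reaction_vectors(labelled_vectors, None, 3) == labelled_vectors

    def test_level3_filter_keeps_matching_class(self, labelled_vectors):
        rec = Recommendation(
            labels=frozenset({parse_label("C-N Bond Formation (Condensation) (Amide)")})
        )
        kept = filter_reaction_vectors(labelled_vectors, rec, 3)
        assert [rv.id for rv in kept] == ["rv0"]

    def test_coarser_level_keeps_superset(self, labelled_vectors):
        rec = Recommendation(
            labels=frozenset({parse_label("C-N Bond Formation (Condensation) (Amide)")})
        )
        by_level = {
            lv: {rv.id for rv in filter_reaction_vectors(labelled_vectors, rec, lv)}
            for lv in (3, 2, 1)
        }
        assert by_level[3] <= by_level[2] <= by_level[1]

    def test_unlabelled_vectors_retained_by_default(self, labelled_vectors):
        import copy

        unl = copy.copy(labelled_vectors[1])
        unl.source_label = None
        rec = Recommendation(labels=frozenset({parse_label("Protection")}))
        kept = filter_reaction_vectors(labelled_vectors + [unl], rec, 1)
        assert unl in kept
        kept_dropping = filter_reaction_vectors(
            labelled_vectors + [unl], rec, 1, drop_unlabelled=True
        )
        assert unl not in kept_dropping


class TestSingleStep:
    def test_empty_vector_list_gives_empty_library(self):
        sms = [mol_from_smiles("CC(=O)O")]
        assert single_step_enumerate(sms, [], []) == []

    def test_template_products_regenerated(self, labelled_vectors):
        rxn = build_reaction(TEMPLATES["amide_coupling"],
                             TEMPLATES["amide_coupling"].sm_pool[0], "NCC")
        sm = rxn.reactants[0]
        reagent = rxn.reactants[1]
        records = single_step_enumerate([sm], [reagent], labelled_vectors[:1])
        recorded = canonical_id(rxn.products[0])
        assert recorded in {r.canonical_id for r in records}

    def test_recommended_library_is_subset_of_control(
        self, labelled_vectors, trained_cc_model
    ):
        sms = [
            mol_from_smiles(TEMPLATES["amide_coupling"].sm_pool[1]),
            mol_from_smiles(TEMPLATES["n_alkylation"].sm_pool[1]),
            mol_from_smiles(TEMPLATES["nitro_reduction"].sm_pool[1]),
        ]
        reagents = [mol_from_smiles(s) for s in ("NCC", "OCC", "BrCC")]
        control = single_step_enumerate(sms, reagents, labelled_vectors)
        filtered = single_step_enumerate(
            sms, reagents, labelled_vectors, model=trained_cc_model, level=3
        )
        ids = lambda rs: {r.canonical_id for r in rs}
        assert ids(filtered) <= ids(control)
        assert len(filtered) <= len(control)


class TestLibraryStats:
    def make_records(self, ids, labels=None):
        labels = labels or [None] * len(ids)
        return [
            ProductRecord(
                product=mol_from_smiles("CC"),
                canonical_id=i,
                sm_id="sm",
                reagent_id=None,
                rv_id="rv",
                rv_label=l,
            )
            for i, l in zip(ids, labels)
        ]

    def test_duplicates_removed(self):
        stats = library_stats(self.make_records(["a", "b", "a", "c", "c"]))
        assert stats.n_unique == 3

    def test_disjoint_reference_zero_overlap(self):
        stats = library_stats(
            self.make_records(["a", "b"]), reference_ids={"x", "y"}
        )
        assert stats.overlap_pct == 0.0

    def test_overlap_percentage(self):
        stats = library_stats(
            self.make_records(["a", "b", "c", "d"]), reference_ids={"a", "b"}
        )
        assert stats.overlap_pct == pytest.approx(50.0)

    def test_single_class_composition(self):
        label = parse_label("C-N Bond Formation (Condensation) (Amide)")
        stats = library_stats(self.make_records(["a", "b"], [label, label]))
        assert stats.class_composition == {"C-N Bond Formation": 1.0}

    def test_composition_sums_to_one(self, labelled_vectors):
        labels = [rv.source_label for rv in labelled_vectors]
        stats = library_stats(self.make_records(list("abcd"), labels))
        assert sum(stats.class_composition.values()) == pytest.approx(1.0)

    def test_failing_scorer_omitted(self):
        def bad(mol):
            raise RuntimeError("boom")

        stats = library_stats(
            self.make_records(["a"]), scorers={"bad": bad, "natoms": lambda m: m.GetNumAtoms()}
        )
        assert "bad" not in stats.external_scores
        assert stats.external_scores["natoms"] == 2.0


class TestFragmentation:
    def test_ranked_by_attachment_points_then_size(self):
        ref = mol_from_smiles("O=C(NCCc1ccc(OCc2ccccc2)cc1)C1CCCC1")
        frags = fragment_reference(ref, RenateConfig())
        n_attach = [
            sum(1 for a in f.GetAtoms() if a.GetAtomicNum() == 0) for f in frags
        ]
        n_heavy = [
            sum(1 for a in f.GetAtoms() if a.GetAtomicNum() > 1) for f in frags
        ]
        assert n_attach == sorted(n_attach, reverse=True)
        for a, b in zip(range(len(frags) - 1), range(1, len(frags))):
            if n_attach[a] == n_attach[b]:
                assert n_heavy[a] >= n_heavy[b]

    def test_min_fragment_size_respected(self):
        ref = mol_from_smiles("O=C(NCCc1ccc(OCc2ccccc2)cc1)C1CCCC1")
        for f in fragment_reference(ref, RenateConfig(min_fragment_atoms=5)):
            assert sum(1 for a in f.GetAtoms() if a.GetAtomicNum() > 1) >= 5

    def test_uncleavable_molecule_returned_whole(self):
        ref = mol_from_smiles("c1ccccc1")
        frags = fragment_reference(ref, RenateConfig())
        assert len(frags) == 1
        assert Chem.MolToSmiles(frags[0]) == "c1ccccc1"

    def test_small_reference_single_fragment(self):
        ref = mol_from_smiles("CCOCC")  # both sides below the minimum
        assert len(fragment_reference(ref, RenateConfig())) == 1


class TestRetrieval:
    def test_exact_fragment_ranks_first(self):
        frag = mol_from_smiles("[1*]CCc1ccccc1")
        pool = [mol_from_smiles(s) for s in ("CCc1ccccc1", "CCCCCC", "c1ccncc1")]
        top = retrieve_analogs(frag, pool, k=1)
        assert canonical_id(top[0]) == canonical_id(pool[0])

    def test_knn_matches_brute_force(self):
        frag = mol_from_smiles("[1*]c1ccc(C)cc1")
        pool_smiles = [
            "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1", "CCCCC", "CCCCCC",
            "c1ccncc1", "Cc1ccc(C)cc1", "CC(C)c1ccccc1", "CCO", "CCCO",
        ]
        pool = [mol_from_smiles(s) for s in pool_smiles]
        got = retrieve_analogs(frag, pool, k=3)
        query = strip_attachment_points(frag)
        qfp = count_fingerprint(query)
        dists = sorted(
            (count_distance(count_fingerprint(m), qfp), Chem.MolToSmiles(m))
            for m in pool + [query]
        )
        # distinct canonical structures only
        seen, expected = set(), []
        for d, smi in dists:
            if smi not in seen:
                seen.add(smi)
                expected.append(smi)
        assert [Chem.MolToSmiles(m) for m in got] == expected[:3]

    def test_k_larger_than_pool_returns_all(self):
        frag = mol_from_smiles("[1*]CC")
        pool = [mol_from_smiles("CCC")]
        got = retrieve_analogs(frag, pool, k=10)
        assert len(got) == 2  # pool member + injected stripped fragment


class TestRenate:
    def test_missing_fragments_block_rediscovery(self):
        case = generate_renate_case(0)
        ref = mol_from_smiles(case.target)
        # remove the exact building blocks from the pool
        blocks = {
            canonical_id(mol_from_smiles(s))
            for s in ("OC(=O)C1CCCC1", "NCCc1ccc(O)cc1", "BrCc1ccccc1")
        }
        pool = [
            mol_from_smiles(s)
            for s in case.pool
            if canonical_id(mol_from_smiles(s)) not in blocks
        ]
        cfg = RenateConfig(beam_width=5)
        _, rediscovered = renate_run(ref, pool, case.vectors, cfg=cfg)
        assert not rediscovered

    def test_single_fragment_reference_checks_pool(self):
        ref = mol_from_smiles("c1ccccc1")
        pool = [mol_from_smiles("c1ccccc1"), mol_from_smiles("CCO")]
        records, rediscovered = renate_run(ref, pool, [], cfg=RenateConfig())
        assert records == [] and rediscovered
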