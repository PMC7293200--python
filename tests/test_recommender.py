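"""Problem-transformation strategies, micro metrics, three-outcome scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.ensemble import RandomForestClassifier

from rvdesign.dataset import MultiLabelDataset, TrainingEntry
from rvdesign.descriptors import BitFingerprint
from rvdesign.labels import LabelVocabulary, ReactionClassLabel, parse_label
from rvdesign.recommender import (
    BaseLearnerSpec,
    ConfusionCounts,
    EvaluationReport,
    Recommendation,
    StrategyConfig,
    evaluate_three_outcome,
    fit,
    load_model,
    micro_metrics,
    predict,
    predict_matrix,
    save_model,
)

SCHEME = "synthetic-bits"


def identity_dataset(n_labels=6, repeats=4):
    """bit i <-> label i: a perfectly separable synthetic mapping.

    Each entry switches on one or two bits and carries exactly the
    matching labels; fingerprints are padded with noise-free context bits
    so entries stay unique.
    """
    labels = tuple(
        ReactionClassLabel((f"Class {i}",)) for i in range(n_labels)
    )
    vocab = LabelVocabulary(level=1, labels=labels)
    n_bits = n_labels + repeats
    rows = []
    for r in range(repeats):
        for i in range(n_labels):
            rows.append((frozenset({i, n_labels + r}), frozenset({i})))
        for i in range(n_labels - 1):
            rows.append(
                (frozenset({i, i + 1, n_labels + r}), frozenset({i, i + 1}))
            )
    entries = []
    X = np.zeros((len(rows), n_bits), dtype=np.uint8)
    Y = np.zeros((len(rows), n_labels), dtype=np.uint8)
    for row, (bits, labs) in enumerate(rows):
        entries.append(
            TrainingEntry(
                fingerprint=BitFingerprint(SCHEME, n_bits, bits),
                labels=frozenset(labels[i] for i in labs),
                member_count=1,
            )
        )
        X[row, sorted(bits)] = 1
        for i in labs:
            Y[row, i] = 1
    return MultiLabelDataset(entries=entries, vocabulary=vocab, X=X, Y=Y, scheme=SCHEME)


class TestStrategyStructure:
    def test_rakeld_partitions_vocabulary(self):
        ds = identity_dataset(n_labels=10)
        model = fit(ds, StrategyConfig(strategy="rakeld", labelset_size=3, seed=0))
        sets = model.labelsets
        assert len(sets) == 4
        assert sorted(len(s) for s in sets) == [1, 3, 3, 3]
        flat = [j for s in sets for j in s]
        assert sorted(flat) == list(range(10))

    def test_rakelo_default_count_and_size(self):
        ds = identity_dataset(n_labels=10)
        model = fit(ds, StrategyConfig(strategy="rakelo", labelset_size=3, seed=0))
        assert len(model.labelsets) == 20  # 2 x |vocabulary|
        assert all(len(s) == 3 for s in model.labelsets)

    def test_learner_counts(self):
        ds = identity_dataset(n_labels=6)
        for strat in ("br", "cc"):
            model = fit(ds, StrategyConfig(strategy=strat, seed=0))
            assert len(model.learners) == 6

    def test_label_without_positives_becomes_constant_negative(self):
        ds = identity_dataset(n_labels=4)
        Y = ds.Y.copy()
        Y[:, 2] = 0
        # keep at least one label per row
        Y[:, 0] |= ~Y.any(axis=1)
        crippled = MultiLabelDataset(
            entries=ds.entries, vocabulary=ds.vocabulary, X=ds.X, Y=Y, scheme=ds.scheme
        )
        model = fit(crippled, StrategyConfig(strategy="br", seed=0))
        assert predict_matrix(model, ds.X)[:, 2].sum() == 0


class TestChainDegeneracy:
    def test_blinded_chain_equals_binary_relevance(self):
        ds = identity_dataset(n_labels=6)
        d = ds.X.shape[1]

        class Blinded:
            """Sees only the original descriptor columns."""

            def __init__(self, seed):
                self.inner = RandomForestClassifier(
                    n_estimators=10, random_state=seed
                )

            def fit(self, X, y):
                self.inner.fit(np.asarray(X)[:, :d], y)
                return self

            def predict(self, X):
                return self.inner.predict(np.asarray(X)[:, :d])

        base = BaseLearnerSpec(factory=lambda seed: Blinded(seed))
        br = fit(ds, StrategyConfig(strategy="br", seed=3), base)
        cc = fit(ds, StrategyConfig(strategy="cc", seed=3), base)
        assert np.array_equal(predict_matrix(br, ds.X), predict_matrix(cc, ds.X))


class TestRecovery:
    @pytest.mark.parametrize("strategy", ["br", "cc", "rakeld", "rakelo"])
    def test_perfect_separable_recovery(self, strategy):
        ds = identity_dataset(n_labels=6)
        model = fit(ds, StrategyConfig(strategy=strategy, seed=0))
        _, rep = micro_metrics(ds.Y, predict_matrix(model, ds.X))
        assert rep.micro_f1 >= 0.99

    def test_two_bit_entry_recovers_both_labels(self):
        ds = identity_dataset(n_labels=8)
        model = fit(ds, StrategyConfig(strategy="br", seed=0))
        fp = BitFingerprint(SCHEME, ds.X.shape[1], frozenset({3, 7, 8}))
        rec = predict(model, fp)
        names = {str(l) for l in rec.labels}
        assert {"Class 3", "Class 7"} <= names

    def test_determinism(self):
        ds = identity_dataset(n_labels=6)
        for strategy in ("br", "cc", "rakeld", "rakelo"):
            m1 = fit(ds, StrategyConfig(strategy=strategy, seed=9))
            m2 = fit(ds, StrategyConfig(strategy=strategy, seed=9))
            assert np.array_equal(predict_matrix(m1, ds.X), predict_matrix(m2, ds.X))

    def test_scheme_mismatch_raises(self):
        ds = identity_dataset()
        model = fit(ds, StrategyConfig(strategy="br", seed=0))
        with pytest.raises(ValueError):
            predict(model, BitFingerprint("other", 10, frozenset()))


def brute_force_micro(Y_true, Y_pred):
    tp = fp = fn = tn = 0
    for i in range(Y_true.shape[0]):
        for j in range(Y_true.shape[1]):
            t, p = bool(Y_true[i, j]), bool(Y_pred[i, j])
            tp += t and p
            fp += (not t) and p
            fn += t and (not p)
            tn += (not t) and (not p)
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * recall * precision / (recall + precision) if recall + precision else 0.0
    return tp, fp, fn, tn, recall, precision, f1


class TestMicroMetrics:
    def test_table_values(self):
        # TP=3, FP=1, FN=2 -> R=0.6, P=0.75, F1=2/3
        Y_true = np.array([[1, 1, 1, 1, 1, 0]])
        Y_pred = np.array([[1, 1, 1, 0, 0, 1]])
        counts, rep = micro_metrics(Y_true, Y_pred)
        assert (counts.TP, counts.FP, counts.FN) == (3, 1, 2)
        assert rep.micro_recall == pytest.approx(0.6)
        assert rep.micro_precision == pytest.approx(0.75)
        assert rep.micro_f1 == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        Y = np.array([[1, 0], [0, 1]])
        _, rep = micro_metrics(Y, Y)
        assert rep.micro_recall == rep.micro_precision == rep.micro_f1 == 1.0

    def test_zero_denominators_give_zero(self):
        Y_true = np.array([[1, 1]])
        Y_pred = np.array([[0, 0]])
        _, rep = micro_metrics(Y_true, Y_pred)
        assert rep.micro_recall == rep.micro_precision == rep.micro_f1 == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            micro_metrics(np.zeros((2, 3)), np.zeros((3, 2)))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30)
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        Y_true = rng.integers(0, 2, size=(20, 8))
        Y_pred = rng.integers(0, 2, size=(20, 8))
        counts, rep = micro_metrics(Y_true, Y_pred)
        tp, fp, fn, tn, r, p, f1 = brute_force_micro(Y_true, Y_pred)
        assert (counts.TP, counts.FP, counts.FN, counts.TN) == (tp, fp, fn, tn)
        assert counts.total == Y_true.size
        assert rep.micro_recall == pytest.approx(r)
        assert rep.micro_precision == pytest.approx(p)
        assert rep.micro_f1 == pytest.approx(f1)

    def test_matches_sklearn(self):
        from sklearn.metrics import f1_score, precision_score, recall_score

        rng = np.random.default_rng(0)
        Y_true = rng.integers(0, 2, size=(30, 6))
        Y_pred = rng.integers(0, 2, size=(30, 6))
        _, rep = micro_metrics(Y_true, Y_pred)
        assert rep.micro_recall == pytest.approx(recall_score(Y_true, Y_pred, average="micro"))
        assert rep.micro_precision == pytest.approx(
            precision_score(Y_true, Y_pred, average="micro")
        )
        assert rep.micro_f1 == pytest.approx(f1_score(Y_true, Y_pred, average="micro"))


class TestThreeOutcome:
    @pytest.fixture()
    def model(self):
        return fit(identity_dataset(n_labels=6), StrategyConfig(strategy="br", seed=0))

    def fp(self, ds_bits, n_bits=10):
        return BitFingerprint(SCHEME, n_bits, frozenset(ds_bits))

    def test_outcomes_partition(self, model):
        vocab = model.vocabulary.labels
        annotated = [
            (self.fp({0, 6}), vocab[0]),   # correct
            (self.fp({1, 6}), vocab[4]),   # wrong
            (self.fp(set()), vocab[2]),    # no-recommendation
        ]
        rep = evaluate_three_outcome(model, annotated)
        assert rep.correct_pct + rep.wrong_pct + rep.norec_pct == pytest.approx(100.0)
        assert rep.correct_pct == pytest.approx(100 / 3)
        assert rep.norec_pct == pytest.approx(100 / 3)

    def test_mean_recommendation_counts(self, model):
        vocab = model.vocabulary.labels
        annotated = [
            (self.fp({0, 6}), vocab[0]),
            (self.fp(set()), vocab[1]),
        ]
        rep = evaluate_three_outcome(model, annotated)
        assert rep.mean_recs_nonempty >= rep.mean_recs_all

    def test_coarser_level_can_rescue(self):
        # truth and prediction share a level-1 parent
        labels = (
            parse_label("C-C Bond Formation (Coupling) (Suzuki)"),
            parse_label("C-C Bond Formation (Coupling) (Heck)"),
        )
        vocab = LabelVocabulary(level=3, labels=labels)
        X = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        Y = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        entries = [
            TrainingEntry(BitFingerprint(SCHEME, 2, frozenset({0})), frozenset({labels[0]}), 1),
            TrainingEntry(BitFingerprint(SCHEME, 2, frozenset({1})), frozenset({labels[1]}), 1),
        ]
        ds = MultiLabelDataset(entries=entries, vocabulary=vocab, X=X, Y=Y, scheme=SCHEME)
        model = fit(ds, StrategyConfig(strategy="br", seed=0))
        annotated = [(BitFingerprint(SCHEME, 2, frozenset({0})), labels[1])]
        at3 = evaluate_three_outcome(model, annotated, level=3)
        at1 = evaluate_three_outcome(model, annotated, level=1)
        assert at3.wrong_pct == 100.0
        assert at1.correct_pct == 100.0


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        ds = identity_dataset(n_labels=5)
        model = fit(ds, StrategyConfig(strategy="rakelo", seed=4))
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        assert np.array_equal(predict_matrix(model, ds.X), predict_matrix(back, ds.X))
        assert back.vocabulary == model.vocabulary

    def test_version_mismatch_refused(self, tmp_path):
        ds = identity_dataset(n_labels=4)
        model = fit(ds, StrategyConfig(strategy="br", seed=0))
        save_model(model, tmp_path / "model")
        manifest = tmp_path / "model" / "manifest.json"
        manifest.write_text(manifest.read_text().replace("rvdesign-model-1", "other"))
        with pytest.raises(ValueError):
            load_model(tmp_path / "model")
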