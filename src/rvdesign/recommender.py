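"""Multi-label reaction class recommender.

The recommender maps a starting-material fingerprint to a (possibly
empty) set of recommended reaction classes.  Multi-label learning is
recast as binary/multi-class problems via problem transformation:

* **BR** (binary relevance): one independent binary learner per label.
* **CC** (classifier chain): like BR, but learner *i* sees the labels of
  the earlier links as extra feature columns (true labels during
  training, its own predictions at inference), linking the labels.
* **RAkELd / RAkELo**: ensembles of label-powerset learners over random
  label subsets of size *k* — disjoint subsets partitioning the
  vocabulary (d) or ``model_count`` possibly-overlapping subsets with a
  per-label majority vote (o).

An empty prediction set is a meaningful outcome ("no recommendation"):
every binary decision came back negative.  Downstream design code treats
it as "apply no filter".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import comb
from pathlib import Path
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC

from .dataset import MultiLabelDataset
from .descriptors import BitFingerprint
from .labels import LabelVocabulary, ReactionClassLabel, parse_label, truncate_label

__all__ = [
    "BaseLearnerSpec",
    "StrategyConfig",
    "RecommenderModel",
    "Recommendation",
    "ConfusionCounts",
    "EvaluationReport",
    "fit",
    "predict",
    "predict_matrix",
    "micro_metrics",
    "evaluate_three_outcome",
    "save_model",
    "load_model",
]

MODEL_VERSION = "rvdesign-model-1"

STRATEGIES = ("br", "cc", "rakeld", "rakelo")


def label_powerset_size(n_labels: int) -> int:
    """Maximum number of label-sets a full Label Powerset could form.

    Every subset of the vocabulary is a potential derived class, so the
    bound is 2**n; the realised number is far smaller, but the bound is
    what makes plain LP infeasible on large vocabularies and motivates
    the RAkEL ensembles over small random label subsets.
    """
    if n_labels < 0:
        raise ValueError("n_labels must be non-negative")
    return 2 ** n_labels


@dataclass(frozen=True)
class BaseLearnerSpec:
    """A deterministic binary/multi-class base learner.

    ``rf`` is a small random forest (10 gini trees, sqrt features,
    bootstrap) and ``svm`` a linear-margin classifier (squared hinge,
    C=1); both accept a seed.  A custom ``factory`` (seed -> estimator)
    overrides the built-ins.
    """

    kind: str = "rf"
    params: Optional[Dict] = None
    factory: Optional[Callable[[int], object]] = None

    def build(self, seed: int):
        if self.factory is not None:
            return self.factory(seed)
        params = dict(self.params or {})
        if self.kind == "rf":
            defaults = dict(
                n_estimators=10,
                criterion="gini",
                max_depth=None,
                min_samples_split=2,
                min_samples_leaf=1,
                min_weight_fraction_leaf=0.0,
                max_features="sqrt",
                max_leaf_nodes=None,
                min_impurity_decrease=0.0,
                bootstrap=True,
                oob_score=False,
                n_jobs=1,
                class_weight=None,
            )
            defaults.update(params)
            return RandomForestClassifier(random_state=seed, **defaults)
        if self.kind == "svm":
            defaults = dict(
                penalty="l2",
                loss="squared_hinge",
                dual=True,
                tol=1e-4,
                C=1.0,
                multi_class="ovr",
                fit_intercept=True,
                intercept_scaling=1,
                class_weight=None,
                max_iter=1000,
            )
            defaults.update(params)
            return LinearSVC(random_state=seed, **defaults)
        raise ValueError(f"unknown base learner kind {self.kind!r}")


@dataclass(frozen=True)
class StrategyConfig:
    strategy: str
    labelset_size: int = 3
    model_count: Optional[int] = None  # RAkELo; default 2 x |vocabulary|
    chain_order: Optional[Tuple[int, ...]] = None  # CC; default vocabulary order
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.labelset_size < 1:
            raise ValueError("labelset_size must be >= 1")
        if self.model_count is not None and self.model_count < 1:
            raise ValueError("model_count must be >= 1")


class _ConstantPredictor:
    """Stand-in learner for labels with no positive training example."""

    def __init__(self, value: int):
        self.value = value

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.value, dtype=int)


class _LabelPowerset:
    """One multi-class learner over the observed label combinations of a subset."""

    def __init__(self, subset: Tuple[int, ...]):
        self.subset = subset
        self.classes_: List[Tuple[int, ...]] = []
        self.learner = None

    def fit(self, X: np.ndarray, Y: np.ndarray, base: BaseLearnerSpec, seed: int):
        sub = Y[:, list(self.subset)]
        combos = [tuple(int(v) for v in row) for row in sub]
        self.classes_ = sorted(set(combos))
        index = {c: i for i, c in enumerate(self.classes_)}
        y = np.array([index[c] for c in combos])
        if len(self.classes_) == 1:
            self.learner = _ConstantPredictor(0)
        else:
            self.learner = base.build(seed)
            self.learner.fit(X, y)
        return self

    def predict_bits(self, X: np.ndarray) -> np.ndarray:
        """(n, len(subset)) binary matrix for this subset's labels."""
        pred = self.learner.predict(X)
        return np.array([self.classes_[int(i)] for i in pred], dtype=np.uint8)


@dataclass
class RecommenderModel:
    config: StrategyConfig
    vocabulary: LabelVocabulary
    scheme: str
    learners: List
    labelsets: Optional[List[Tuple[int, ...]]] = None  # RAkEL variants
    chain_order: Optional[Tuple[int, ...]] = None      # CC
    version: str = MODEL_VERSION

    @property
    def level(self) -> int:
        return self.vocabulary.level


def _fit_binary(X: np.ndarray, y: np.ndarray, base: BaseLearnerSpec, seed: int):
    if y.sum() == 0:
        return _ConstantPredictor(0)
    if y.sum() == len(y):
        return _ConstantPredictor(1)
    learner = base.build(seed)
    learner.fit(X, y)
    return learner


def fit(
    ds: MultiLabelDataset,
    config: StrategyConfig,
    base: BaseLearnerSpec = BaseLearnerSpec("rf"),
) -> RecommenderModel:
    """Train a recommender with the requested problem transformation."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    X = np.asarray(ds.X)
    Y = np.asarray(ds.Y)
    L = len(ds.vocabulary)
    rng = np.random.default_rng(config.seed)

    if config.strategy == "br":
        learners = [_fit_binary(X, Y[:, j], base, config.seed) for j in range(L)]
        return RecommenderModel(config, ds.vocabulary, ds.scheme, learners)

    if config.strategy == "cc":
        order = config.chain_order or tuple(range(L))
        if sorted(order) != list(range(L)):
            raise ValueError("chain_order must be a permutation of the vocabulary")
        learners = []
        Xa = X
        for j in order:
            learners.append(_fit_binary(Xa, Y[:, j], base, config.seed))
            Xa = np.hstack([Xa, Y[:, [j]]])
        return RecommenderModel(
            config, ds.vocabulary, ds.scheme, learners, chain_order=tuple(order)
        )

    k = min(config.labelset_size, L)
    if config.strategy == "rakeld":
        perm = rng.permutation(L)
        labelsets = [
            tuple(int(v) for v in sorted(perm[i : i + k]))
            for i in range(0, L, k)
        ]
    else:  # rakelo
        count = config.model_count or 2 * L
        n_possible = comb(L, k)
        chosen: List[Tuple[int, ...]] = []
        seen = set()
        attempts = 0
        while len(chosen) < count and attempts < 50 * count:
            cand = tuple(int(v) for v in sorted(rng.choice(L, size=k, replace=False)))
            attempts += 1
            if cand in seen and len(seen) < n_possible:
                continue
            seen.add(cand)
            chosen.append(cand)
        while len(chosen) < count:  # tiny vocabularies: reuse deterministically
            chosen.append(chosen[len(chosen) % max(len(chosen), 1)])
        labelsets = chosen
    learners = [
        _LabelPowerset(subset).fit(X, Y, base, config.seed) for subset in labelsets
    ]
    return RecommenderModel(
        config, ds.vocabulary, ds.scheme, learners, labelsets=labelsets
    )


def predict_matrix(model: RecommenderModel, X: np.ndarray) -> np.ndarray:
    """Binary label predictions, one row per input row."""
    X = np.asarray(X)
    L = len(model.vocabulary)
    n = X.shape[0]
    cfg = model.config
    if cfg.strategy == "br":
        out = np.zeros((n, L), dtype=np.uint8)
        for j, learner in enumerate(model.learners):
            out[:, j] = learner.predict(X)
        return out
    if cfg.strategy == "cc":
        out = np.zeros((n, L), dtype=np.uint8)
        Xa = X
        for learner, j in zip(model.learners, model.chain_order):
            pred = np.asarray(learner.predict(Xa), dtype=np.uint8)
            out[:, j] = pred
            Xa = np.hstack([Xa, pred[:, None]])
        return out
    # RAkEL variants: per-label vote over the covering subsets; a label is
    # positive iff strictly more than half its covering subsets vote yes
    # (no covering subset -> negative).
    votes = np.zeros((n, L), dtype=int)
    covering = np.zeros(L, dtype=int)
    for learner in model.learners:
        bits = learner.predict_bits(X)
        for pos, j in enumerate(learner.subset):
            votes[:, j] += bits[:, pos]
            covering[j] += 1
    out = np.zeros((n, L), dtype=np.uint8)
    nz = covering > 0
    out[:, nz] = (votes[:, nz] * 2 > covering[nz]).astype(np.uint8)
    return out


@dataclass(frozen=True)
class Recommendation:
    labels: FrozenSet[ReactionClassLabel]

    def __bool__(self) -> bool:
        return bool(self.labels)

    @property
    def is_empty(self) -> bool:
        return not self.labels


def predict(model: RecommenderModel, fp: BitFingerprint) -> Recommendation:
    if fp.scheme != model.scheme:
        raise ValueError(f"scheme mismatch: {fp.scheme} vs model {model.scheme}")
    row = predict_matrix(model, fp.to_array()[None, :])[0]
    labels = frozenset(
        model.vocabulary.labels[j] for j in np.flatnonzero(row)
    )
    return Recommendation(labels=labels)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class EvaluationReport:
    micro_recall: Optional[float] = None
    micro_precision: Optional[float] = None
    micro_f1: Optional[float] = None
    correct_pct: Optional[float] = None
    wrong_pct: Optional[float] = None
    norec_pct: Optional[float] = None
    mean_recs_all: Optional[float] = None
    mean_recs_nonempty: Optional[float] = None

    def to_dict(self) -> Dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def micro_metrics(
    Y_true: np.ndarray, Y_pred: np.ndarray
) -> Tuple[ConfusionCounts, EvaluationReport]:
    """Micro-averaged recall/precision/F1 from globally pooled counts.

    Zero denominators yield 0 so that the metrics are total functions.
    """
    Y_true = np.asarray(Y_true).astype(bool)
    Y_pred = np.asarray(Y_pred).astype(bool)
    if Y_true.shape != Y_pred.shape:
        raise ValueError(f"shape mismatch: {Y_true.shape} vs {Y_pred.shape}")
    tp = int(np.sum(Y_true & Y_pred))
    fp = int(np.sum(~Y_true & Y_pred))
    fn = int(np.sum(Y_true & ~Y_pred))
    tn = int(np.sum(~Y_true & ~Y_pred))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (
        2 * recall * precision / (recall + precision)
        if recall + precision
        else 0.0
    )
    counts = ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)
    return counts, EvaluationReport(
        micro_recall=recall, micro_precision=precision, micro_f1=f1
    )


def evaluate_three_outcome(
    model: RecommenderModel,
    annotated: Sequence[Tuple[BitFingerprint, ReactionClassLabel]],
    level: Optional[int] = None,
) -> EvaluationReport:
    """Correct / wrong / no-recommendation bookkeeping.

    An entry is *correct* when the recommendation set, compared at the
    requested level of the hierarchy, contains the annotated class;
    *no-recommendation* when the set is empty; *wrong* otherwise.  Mean
    recommendation counts are reported over all entries and over the
    entries that received at least one recommendation.
    """
    if not annotated:
        raise ValueError("nothing to evaluate")
    level = level or model.level
    n_correct = n_wrong = n_norec = 0
    rec_counts: List[int] = []
    for fp, true_label in annotated:
        rec = predict(model, fp)
        rec_counts.append(len(rec.labels))
        if rec.is_empty:
            n_norec += 1
            continue
        truth = truncate_label(true_label, level)
        hit = any(truncate_label(l, level) == truth for l in rec.labels)
        if hit:
            n_correct += 1
        else:
            n_wrong += 1
    n = len(annotated)
    nonempty = [c for c in rec_counts if c > 0]
    return EvaluationReport(
        correct_pct=100.0 * n_correct / n,
        wrong_pct=100.0 * n_wrong / n,
        norec_pct=100.0 * n_norec / n,
        mean_recs_all=float(np.mean(rec_counts)),
        mean_recs_nonempty=float(np.mean(nonempty)) if nonempty else 0.0,
    )


def save_model(model: RecommenderModel, path: str) -> None:
    """JSON manifest + learner blobs under a directory."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": model.version,
        "scheme": model.scheme,
        "strategy": model.config.strategy,
        "labelset_size": model.config.labelset_size,
        "model_count": model.config.model_count,
        "chain_order": list(model.chain_order) if model.chain_order else None,
        "seed": model.config.seed,
        "level": model.vocabulary.level,
        "labels": [str(l) for l in model.vocabulary.labels],
        "labelsets": [list(s) for s in model.labelsets] if model.labelsets else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    joblib.dump(model.learners, out / "learners.joblib")


def load_model(path: str) -> RecommenderModel:
    src = Path(path)
    manifest = json.loads((src / "manifest.json").read_text())
    if manifest.get("version") != MODEL_VERSION:
        raise ValueError(
            f"model version mismatch: {manifest.get('version')} != {MODEL_VERSION}"
        )
    vocab = LabelVocabulary(
        level=manifest["level"],
        labels=tuple(parse_label(t) for t in manifest["labels"]),
    )
    config = StrategyConfig(
        strategy=manifest["strategy"],
        labelset_size=manifest["labelset_size"],
        model_count=manifest["model_count"],
        chain_order=tuple(manifest["chain_order"]) if manifest["chain_order"] else None,
        seed=manifest["seed"],
    )
    learners = joblib.load(src / "learners.joblib")
    return RecommenderModel(
        config=config,
        vocabulary=vocab,
        scheme=manifest["scheme"],
        learners=learners,
        labelsets=[tuple(s) for s in manifest["labelsets"]]
        if manifest["labelsets"]
        else None,
        chain_order=tuple(manifest["chain_order"]) if manifest["chain_order"] else None,
    )
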