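"""Binary food / non-food post classification on tf-idf features.

Features are unigrams plus detected multiword expressions used as single
features: a matched phrase consumes its unigrams, so ``sweet potato``
contributes one feature ``sweet potato`` rather than two.  The tf-idf
dialect is fixed: raw term counts, smoothed idf = ln((1+N)/(1+df)) + 1,
L2-normalized rows.  Four model families are supported — multinomial
naive Bayes (nb), logistic regression (lr), random forest (rf) and a
linear-kernel SVM (svm) — all deterministic given a seed.

The class order convention for every confusion matrix is
(food, non-food): rows are true classes, columns predictions, and the
false-positive rate is the row-normalized [non-food, food] cell.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .cleaning import CleanPost
from .lexicon import Lexicon
from .phrases import PhraseInventory, extract_content_groups, match_mwe

__all__ = [
    "CLASS_ORDER",
    "MODEL_KINDS",
    "FeatureSpec",
    "EvalReport",
    "LearningCurve",
    "phrase_features",
    "build_features",
    "FoodPostClassifier",
    "train",
    "evaluate",
    "learning_curve",
    "weak_labels",
    "save_model",
    "load_model",
]

CLASS_ORDER = ("food", "non-food")
MODEL_KINDS = ("nb", "lr", "rf", "svm")
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class FeatureSpec:
    """Fitted vocabulary and idf weights of the tf-idf feature space."""

    vocabulary: tuple[str, ...]
    idf: tuple[float, ...]
    norm: str = "l2"

    def to_json(self) -> str:
        return json.dumps(
            {"vocabulary": list(self.vocabulary), "idf": list(self.idf), "norm": self.norm}
        )


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts (rows = true class, order food / non-food),
    row-normalized proportions, accuracy and false-positive rate."""

    confusion: np.ndarray
    row_normalized: np.ndarray
    accuracy: float
    false_positive_rate: float

    def to_dict(self) -> dict:
        return {
            "class_order": list(CLASS_ORDER),
            "confusion": self.confusion.tolist(),
            "row_normalized": self.row_normalized.tolist(),
            "accuracy": self.accuracy,
            "false_positive_rate": self.false_positive_rate,
        }


@dataclass(frozen=True)
class LearningCurve:
    """Held-out accuracy as a function of training-set size."""

    points: tuple[tuple[int, float], ...]
    stderr: tuple[float, ...]
    seeds: tuple[int, ...]


def _identity(doc):
    """Pass-through analyzer: documents are pre-tokenized feature lists.
    Module-level so fitted vectorizers stay picklable."""
    return doc


def phrase_features(post: CleanPost, inventory: PhraseInventory | None) -> list[str]:
    """Feature tokens of one post: residual unigrams plus matched phrase
    forms as single (space-joined) features, in surface order."""
    if inventory is None or len(inventory) == 0:
        return list(post.tokens)
    out: list[str] = []
    for group in extract_content_groups(post.tokens, post.boundaries):
        g = match_mwe(group, inventory)
        consumed = g.matched_positions
        matches = {m.positions[0]: m for m in g.matches}
        for i, tok in enumerate(group.surface_tokens):
            if i in matches:
                out.append(" ".join(matches[i].form))
            elif i not in consumed:
                out.append(tok)
    return out


def build_features(
    corpus: Sequence[CleanPost], inventory: PhraseInventory | None = None
):
    """Fit the phrase-aware tf-idf space on a corpus.

    Returns (FeatureSpec, row-L2-normalized sparse matrix, fitted
    vectorizer).  Raw counts, idf = ln((1+N)/(1+df)) + 1.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    docs = [phrase_features(p, inventory) for p in corpus]
    vectorizer = TfidfVectorizer(
        analyzer=_identity, norm="l2", smooth_idf=True, sublinear_tf=False
    )
    matrix = vectorizer.fit_transform(docs)
    vocab = vectorizer.get_feature_names_out()
    spec = FeatureSpec(vocabulary=tuple(vocab), idf=tuple(float(v) for v in vectorizer.idf_))
    return spec, matrix, vectorizer


def _make_model(kind: str, random_state: int):
    if kind == "nb":
        return MultinomialNB()
    if kind == "lr":
        return LogisticRegression(max_iter=2000, random_state=random_state)
    if kind == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=random_state, n_jobs=1)
    if kind == "svm":
        return LinearSVC(random_state=random_state)
    raise ValueError(f"unknown model kind '{kind}' (expected one of {MODEL_KINDS})")


class FoodPostClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style binary food/non-food classifier over cleaned posts.

    Parameters
    ----------
    kind : {"nb", "lr", "rf", "svm"}
        Model family on top of the tf-idf features.
    inventory : PhraseInventory or None
        Multiword-expression inventory whose matches become single
        features; None disables phrase merging.
    random_state : int
        Seed making fit and predict deterministic.
    """

    def __init__(
        self,
        kind: str = "rf",
        inventory: PhraseInventory | None = None,
        random_state: int = 0,
    ):
        self.kind = kind
        self.inventory = inventory
        self.random_state = random_state

    def fit(self, X: Sequence[CleanPost], y: Sequence[str]) -> "FoodPostClassifier":
        y = np.asarray(y, dtype=object)
        if len(X) != len(y):
            raise ValueError("features and labels are not aligned")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        spec, matrix, vectorizer = build_features(X, self.inventory)
        model = _make_model(self.kind, self.random_state)
        model.fit(matrix, y)
        self.feature_spec_ = spec
        self.vectorizer_ = vectorizer
        self.model_ = model
        self.classes_ = model.classes_
        self.n_features_in_ = matrix.shape[1]
        return self

    def _transform(self, X: Sequence[CleanPost]):
        docs = [phrase_features(p, self.inventory) for p in X]
        return self.vectorizer_.transform(docs)

    def predict(self, X: Sequence[CleanPost]) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(self._transform(X))


def train(
    kind: str,
    corpus: Sequence[CleanPost],
    labels: Sequence[str],
    seed: int = 0,
    inventory: PhraseInventory | None = None,
) -> FoodPostClassifier:
    """Fit a classifier of the given kind; deterministic given ``seed``."""
    return FoodPostClassifier(kind=kind, inventory=inventory, random_state=seed).fit(
        corpus, labels
    )


def evaluate(
    model: FoodPostClassifier, X: Sequence[CleanPost], y: Sequence[str]
) -> EvalReport:
    """Confusion matrix, accuracy and false-positive rate on a test set.

    Both classes must be present so every row normalizes to 1.
    """
    if len(X) == 0:
        raise ValueError("test set is empty")
    y = np.asarray(y, dtype=object)
    if len(np.unique(y)) < 2:
        raise ValueError("test labels contain a single class; rows cannot be normalized")
    pred = model.predict(X)
    counts = confusion_matrix(y, pred, labels=list(CLASS_ORDER))
    row_sums = counts.sum(axis=1, keepdims=True)
    row_normalized = counts / row_sums
    accuracy = float(np.trace(counts) / counts.sum())
    fpr = float(row_normalized[1, 0])  # true non-food predicted food
    return EvalReport(
        confusion=counts,
        row_normalized=row_normalized,
        accuracy=accuracy,
        false_positive_rate=fpr,
    )


def learning_curve(
    kind: str,
    corpus: Sequence[CleanPost],
    labels: Sequence[str],
    sizes: Sequence[int],
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    inventory: PhraseInventory | None = None,
    test_fraction: float = 0.2,
    split_seed: int = 0,
) -> LearningCurve:
    """Mean held-out accuracy per training size over several seeds.

    The held-out split is fixed (stratified, ``split_seed``); per seed, a
    random training subsample of each size is drawn and fitted.  Sizes must
    be strictly increasing and fit within the training partition.
    """
    sizes = list(sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("training sizes must be strictly increasing")
    labels = np.asarray(labels, dtype=object)
    idx = np.arange(len(corpus))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=split_seed, stratify=labels
    )
    if sizes[-1] > len(train_idx):
        raise ValueError(
            f"training size {sizes[-1]} exceeds available {len(train_idx)} samples"
        )
    X_test = [corpus[i] for i in test_idx]
    y_test = labels[test_idx]

    points = []
    stderr = []
    for size in sizes:
        accs = []
        for seed in seeds:
            rng = np.random.default_rng(seed)
            while True:  # resample until both classes present
                sub = rng.choice(train_idx, size=size, replace=False)
                if len(np.unique(labels[sub])) == 2:
                    break
            model = train(kind, [corpus[i] for i in sub], labels[sub], seed=seed, inventory=inventory)
            accs.append(evaluate(model, X_test, y_test).accuracy)
        points.append((size, float(np.mean(accs))))
        stderr.append(float(np.std(accs, ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0)
    return LearningCurve(points=tuple(points), stderr=tuple(stderr), seeds=tuple(seeds))


def weak_labels(
    corpus: Sequence[CleanPost],
    food_lexicon: Lexicon,
    idiom_inventory: PhraseInventory | None = None,
) -> list[str]:
    """Lexicon-derived weak supervision: a post is ``food`` iff at least one
    unmasked token/phrase hits the food lexicon, else ``non-food``."""
    from .calorics import count_mentions

    out = []
    for post in corpus:
        table = count_mentions([post], food_lexicon, idiom_inventory)
        out.append("food" if table.total() > 0 else "non-food")
    return out


def save_model(model: FoodPostClassifier, path: str | Path) -> None:
    """Serialize a fitted classifier with an embedded FeatureSpec manifest."""
    check_is_fitted(model, "model_")
    payload = {
        "format_version": _FORMAT_VERSION,
        "feature_spec": model.feature_spec_.to_json(),
        "kind": model.kind,
        "random_state": model.random_state,
        "estimator": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> FoodPostClassifier:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return payload["estimator"]
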