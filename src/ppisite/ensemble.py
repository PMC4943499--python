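"""Bagging ensemble over decision-tree base learners.

m bootstrap samples (uniform with replacement, size n' = n by default) are
drawn from the training set, one tree is fitted per sample, and prediction
is by majority vote.  The vote fraction for the positive class doubles as a
score for threshold sweeps; a tied vote goes to the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .evaluation import ConfusionCounts, MetricsReport, confusion, metrics

__all__ = [
    "BaggingConfig",
    "BaggingModel",
    "bootstrap_sample",
    "fit_tree",
    "train_bagging",
    "predict_vote",
    "cross_validate",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class BaggingConfig:
    m: int = 10
    n_prime: int | None = None  # None -> n
    seed: int = 0
    tree_params: dict = field(default_factory=lambda: {
        "criterion": "gini",
        "max_depth": None,
        "min_samples_leaf": 2,
    })

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("need at least one base learner")
        if self.n_prime is not None and self.n_prime < 1:
            raise ValueError("bootstrap sample size must be >= 1")


def bootstrap_sample(n: int, n_prime: int, rng: np.random.Generator) -> np.ndarray:
    """n_prime indices drawn i.i.d. uniform with replacement from [0, n)."""
    if n < 1:
        raise ValueError("dataset must be non-empty")
    return rng.integers(0, n, size=n_prime)


def fit_tree(X: np.ndarray, y: np.ndarray, params: dict | None = None,
             seed: int = 0) -> DecisionTreeClassifier:
    """Fit one base learner (CART, Gini, unlimited depth, min leaf 2)."""
    params = dict(params or BaggingConfig().tree_params)
    tree = DecisionTreeClassifier(random_state=seed, **params)
    tree.fit(np.asarray(X), np.asarray(y))
    return tree


@dataclass
class BaggingModel:
    learners: list
    config: BaggingConfig
    n_features: int

    def __post_init__(self) -> None:
        if len(self.learners) != self.config.m:
            raise ValueError("model must hold exactly m learners")


def train_bagging(X: np.ndarray, y: np.ndarray, config: BaggingConfig | None = None,
                  identity_samples: bool = False) -> BaggingModel:
    """Train m trees on m independent bootstrap samples.

    ``identity_samples`` replaces the bootstrap by the full sample (test
    hook: m=1 then degenerates to a single tree).
    """
    config = config or BaggingConfig()
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    n = X.shape[0]
    n_prime = config.n_prime if config.n_prime is not None else n
    rng = np.random.default_rng(config.seed)
    learners = []
    for i in range(config.m):
        if identity_samples:
            idx = np.arange(n)
        else:
            idx = bootstrap_sample(n, n_prime, rng)
        learners.append(fit_tree(X[idx], y[idx], config.tree_params,
                                 seed=config.seed + i))
    return BaggingModel(learners=learners, config=config, n_features=X.shape[1])


def predict_vote(model: BaggingModel, X: np.ndarray):
    """Majority-vote labels and positive-vote fractions.

    Returns (labels, scores); label 1 iff score > 0.5 (ties -> class 0).
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1] if X.ndim == 2 else X.shape}"
        )
    votes = np.zeros(X.shape[0])
    for learner in model.learners:
        votes += (learner.predict(X) == 1)
    scores = votes / len(model.learners)
    labels = (scores > 0.5).astype(int)
    return labels, scores


@dataclass
class FoldResult:
    counts: ConfusionCounts
    report: MetricsReport
    single_class_fold: bool
    test_indices: np.ndarray
    scores: np.ndarray


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Deterministic stratified partition: fold sizes differ by at most 1."""
    folds = [[] for _ in range(k)]
    slot = 0
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        for i in idx:
            folds[slot % k].append(int(i))
            slot += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(X: np.ndarray, y: np.ndarray, k: int = 5,
                   config: BaggingConfig | None = None, seed: int = 0):
    """Stratified k-fold cross-validation of the bagging ensemble.

    Every sample is tested exactly once.  Returns (fold_results,
    pooled_counts, pooled_report); folds whose test part contains a single
    class are flagged and their undefined metrics carry a reason.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    n = len(y)
    if n < k:
        raise ValueError("need at least k samples")
    config = config or BaggingConfig()
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    results: list[FoldResult] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fi, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        fold_config = BaggingConfig(
            m=config.m, n_prime=config.n_prime,
            seed=config.seed + 1000 * fi, tree_params=dict(config.tree_params),
        )
        model = train_bagging(X[train_mask], y[train_mask], fold_config)
        pred, scores = predict_vote(model, X[test_idx])
        counts = confusion(y[test_idx], pred)
        pooled = ConfusionCounts(
            tp=pooled.tp + counts.tp, tn=pooled.tn + counts.tn,
            fp=pooled.fp + counts.fp, fn=pooled.fn + counts.fn,
        )
        results.append(FoldResult(
            counts=counts,
            report=metrics(counts),
            single_class_fold=len(np.unique(y[test_idx])) < 2,
            test_indices=test_idx,
            scores=scores,
        ))
    return results, pooled, metrics(pooled)


def save_model(model: BaggingModel, path) -> None:
    joblib.dump({
        "format_version": MODEL_FORMAT_VERSION,
        "config": model.config,
        "learners": model.learners,
        "n_features": model.n_features,
    }, path)


def load_model(path) -> BaggingModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model archive version")
    return BaggingModel(
        learners=payload["learners"],
        config=payload["config"],
        n_features=payload["n_features"],
    )
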