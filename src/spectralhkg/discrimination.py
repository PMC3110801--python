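"""RBF-kernel SVM classification of power-spectrum features.

Includes grid-search hyperparameter selection and the two-model comparison
experiment: the HN model trains standard-pool positives against randomly
sampled non-HKG negatives, while the NN control model trains two disjoint
random non-HKG samples against each other.  Features are standardised (zero
mean, unit variance, estimated on the training rows) before the RBF kernel
because raw spectral powers span many orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .expression_io import ProbePartition
from .spectral_features import FeatureMatrix

__all__ = [
    "ClassifierSpec",
    "ComparisonResult",
    "TrainedClassifier",
    "DEFAULT_GRID",
    "DEFAULT_SPEC",
    "select_hyperparameters",
    "train_classifier",
    "run_model_comparison",
]


@dataclass(frozen=True, order=True)
class ClassifierSpec:
    """Soft-margin penalty C and RBF kernel width gamma."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be strictly positive")


#: C in 2^-3..2^7, gamma in 2^-9..2^1, both in powers of two.
DEFAULT_GRID: tuple[ClassifierSpec, ...] = tuple(
    ClassifierSpec(C=2.0**i, gamma=2.0**j)
    for i in range(-3, 8)
    for j in range(-9, 2)
)

#: Fixed default reused across voting rounds when no grid search is requested.
DEFAULT_SPEC = ClassifierSpec(C=8.0, gamma=2.0**-7)


def _make_estimator(spec: ClassifierSpec, standardize: bool) -> Pipeline:
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(C=spec.C, gamma=spec.gamma, kernel="rbf")))
    return Pipeline(steps)


def select_hyperparameters(
    features: np.ndarray,
    labels: np.ndarray,
    grid: Sequence[ClassifierSpec] = DEFAULT_GRID,
    folds: int = 5,
    standardize: bool = True,
) -> ClassifierSpec:
    """Pick the grid point with the highest mean k-fold CV accuracy.

    Ties are broken in favour of the smallest C, then the smallest gamma.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < folds:
        raise ValueError(
            f"need >= {folds} examples per class for {folds}-fold CV"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=False)
    best_spec: ClassifierSpec | None = None
    best_score = -np.inf
    for spec in sorted(grid):  # (C, gamma) ascending -> first strict max wins ties
        score = cross_val_score(_make_estimator(spec, standardize), X, y, cv=cv).mean()
        if score > best_score + 1e-12:
            best_score = score
            best_spec = spec
    assert best_spec is not None
    return best_spec


class TrainedClassifier:
    """A fitted binary HKG/non-HKG decision function."""

    def __init__(self, estimator: Pipeline, spec: ClassifierSpec):
        self._estimator = estimator
        self.spec = spec

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean array: True where the row is classified as HKG."""
        return self._estimator.predict(np.asarray(X, dtype=float)) == 1

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._estimator.decision_function(np.asarray(X, dtype=float))

    def accuracy(self, X: np.ndarray, is_hkg: np.ndarray) -> float:
        return float(accuracy_score(np.asarray(is_hkg, dtype=bool), self.predict(X)))


def train_classifier(
    pos: np.ndarray,
    neg: np.ndarray,
    spec: ClassifierSpec,
    standardize: bool = True,
) -> TrainedClassifier:
    """Fit the RBF SVM on positive (HKG) and negative feature rows."""
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(pos.shape[0], dtype=int), np.zeros(neg.shape[0], dtype=int)])
    estimator = _make_estimator(spec, standardize)
    estimator.fit(X, y)
    return TrainedClassifier(estimator, spec)


@dataclass(frozen=True)
class ComparisonResult:
    """Held-out accuracies of the HN (true) and NN (control) models."""

    hn_accuracies: np.ndarray
    nn_accuracies: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        hn = np.asarray(self.hn_accuracies, dtype=float)
        nn = np.asarray(self.nn_accuracies, dtype=float)
        object.__setattr__(self, "hn_accuracies", hn)
        object.__setattr__(self, "nn_accuracies", nn)
        if hn.size != self.n_replicates or nn.size != self.n_replicates:
            raise ValueError("accuracy sequences must have length n_replicates")
        for arr in (hn, nn):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("accuracies must lie in [0, 1]")


def _split_half(rows: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(rows)
    half = rows.size // 2
    return perm[:half], perm[half:]


def _fit_and_score(
    X: np.ndarray,
    pos_rows: np.ndarray,
    neg_rows: np.ndarray,
    spec: ClassifierSpec,
    rng: np.random.Generator,
    standardize: bool,
) -> float:
    """Stratified 50/50 train/test split; returns held-out accuracy."""
    pos_train, pos_test = _split_half(pos_rows, rng)
    neg_train, neg_test = _split_half(neg_rows, rng)
    clf = train_classifier(X[pos_train], X[neg_train], spec, standardize)
    test_rows = np.concatenate([pos_test, neg_test])
    truth = np.concatenate(
        [np.ones(pos_test.size, dtype=bool), np.zeros(neg_test.size, dtype=bool)]
    )
    return clf.accuracy(X[test_rows], truth)


def sample_replicate_rows(
    rng: np.random.Generator,
    standard_rows: np.ndarray,
    non_hkg_rows: np.ndarray,
    n_per_class: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw one replicate's row sets: (hn_pos, hn_neg, nn_pos, nn_neg).

    The three non-HKG samples are drawn without replacement from a single
    permutation, so all four sets are pairwise disjoint within the replicate.
    """
    if standard_rows.size < n_per_class:
        raise ValueError(
            f"standard pool has {standard_rows.size} probes, need {n_per_class}"
        )
    if non_hkg_rows.size < 3 * n_per_class:
        raise ValueError(
            f"non-HKG pool has {non_hkg_rows.size} probes, need {3 * n_per_class}"
        )
    hn_pos = rng.choice(standard_rows, size=n_per_class, replace=False)
    drawn = rng.choice(non_hkg_rows, size=3 * n_per_class, replace=False)
    return hn_pos, drawn[:n_per_class], drawn[n_per_class: 2 * n_per_class], drawn[2 * n_per_class:]


def run_model_comparison(
    features: FeatureMatrix,
    partition: ProbePartition,
    n_replicates: int,
    n_per_class: int,
    spec: ClassifierSpec,
    seed: int,
    standardize: bool = True,
) -> ComparisonResult:
    """Replicate the HN-vs-NN experiment and collect held-out accuracies.

    Each replicate samples fresh class rows, splits each class 50/50 into
    train/test halves, fits both models, and records their test accuracies.
    Fully deterministic for a given seed.
    """
    if n_replicates < 1 or n_per_class < 2:
        raise ValueError("need n_replicates >= 1 and n_per_class >= 2")
    standard_rows = features.rows_for(sorted(partition.standard & set(features.probe_ids)))
    non_hkg_rows = features.rows_for(sorted(partition.non_hkg & set(features.probe_ids)))
    rng = np.random.default_rng(seed)
    X = features.values
    hn_acc = np.empty(n_replicates)
    nn_acc = np.empty(n_replicates)
    for r in range(n_replicates):
        hn_pos, hn_neg, nn_pos, nn_neg = sample_replicate_rows(
            rng, standard_rows, non_hkg_rows, n_per_class
        )
        hn_acc[r] = _fit_and_score(X, hn_pos, hn_neg, spec, rng, standardize)
        nn_acc[r] = _fit_and_score(X, nn_pos, nn_neg, spec, rng, standardize)
    return ComparisonResult(hn_accuracies=hn_acc, nn_accuracies=nn_acc, n_replicates=n_replicates)
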