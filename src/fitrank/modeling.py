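"""Discriminative models and the multi-seed replication harness.

Classification uses L2-penalised logistic regression (a deliberately simple
model so encodings compete on even footing); regression uses a random-forest
regressor whose ``n_estimators`` / ``max_depth`` are chosen by a budgeted
random search on an internal validation split. :func:`run_replicates` runs
every (encoding x sampler x combiner) alternative over a shared per-seed
train/test split so comparisons are paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .datatypes import EncodingMatrix
from .ensemble import concat_encodings, majority_vote
from .exceptions import FitrankError, SingleClassError
from .metrics import MetricReport, classification_metrics, regression_metrics
from .sampling import SplitSpec, resample_by_name, stratified_split_indices

__all__ = [
    "ClassifierSpec",
    "RegressorSpec",
    "FittedClassifier",
    "FittedRegressor",
    "Alternative",
    "ReplicateTable",
    "train_classifier",
    "evaluate_classifier",
    "fit_regressor",
    "run_replicates",
]


@dataclass(frozen=True)
class ClassifierSpec:
    regularization_strength: float = 1.0  # lambda; sklearn C = 1 / lambda
    max_iterations: int = 1000
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.regularization_strength <= 0:
            raise FitrankError("regularization strength must be positive")


@dataclass(frozen=True)
class RegressorSpec:
    n_estimators_range: tuple[int, int] = (50, 300)
    max_depth_range: tuple[int, int] = (2, 20)
    search_budget: int = 25
    validation_fraction: float = 0.2


class FittedClassifier:
    """Fitted logistic model plus its (train-only) standardization parameters."""

    def __init__(self, model: LogisticRegression, scaler: StandardScaler | None):
        self._model = model
        self._scaler = scaler

    @property
    def standardized(self) -> bool:
        return self._scaler is not None

    @property
    def coefficients(self) -> np.ndarray:
        return self._model.coef_.ravel()

    def _transform(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        return self._scaler.transform(features) if self._scaler else features

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self._model.predict(self._transform(features))

    def predict_proba_positive(self, features: np.ndarray) -> np.ndarray:
        proba = self._model.predict_proba(self._transform(features))
        positive_column = list(self._model.classes_).index(1)
        return proba[:, positive_column]


def train_classifier(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
    seed: int = 0,
) -> FittedClassifier:
    """Fit an L2 logistic regression; non-convergence warns with the iteration cap."""
    features = np.asarray(train_features, dtype=float)
    labels = np.asarray(train_labels)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("training labels contain a single class")
    scaler = None
    if spec.standardize:
        scaler = StandardScaler()
        features = scaler.fit_transform(features)
    model = LogisticRegression(
        penalty="l2",
        C=1.0 / spec.regularization_strength,
        max_iter=spec.max_iterations,
        solver="lbfgs",
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(features, labels)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        warnings.warn(
            f"logistic regression did not converge within {spec.max_iterations} iterations",
            stacklevel=2,
        )
    return FittedClassifier(model=model, scaler=scaler)


def evaluate_classifier(
    handle: FittedClassifier, test_features: np.ndarray, test_labels: np.ndarray
) -> MetricReport:
    """Score a fitted classifier on a held-out test set."""
    test_labels = np.asarray(test_labels)
    if len(test_labels) == 0:
        raise FitrankError("cannot evaluate on an empty test set")
    return classification_metrics(test_labels, handle.predict(test_features))


class FittedRegressor:
    def __init__(self, model: RandomForestRegressor):
        self._model = model

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self._model.predict(np.asarray(features, dtype=float))


def fit_regressor(
    train_features: np.ndarray,
    train_targets: np.ndarray,
    spec: RegressorSpec = RegressorSpec(),
    seed: int = 0,
) -> tuple[FittedRegressor, dict[str, int], "object"]:
    """Budgeted random hyperparameter search for a random-forest regressor.

    Returns the refitted best model, its chosen hyperparameters, and the
    validation :class:`~fitrank.metrics.RegressionReport` of the winner
    (best by validation MSE).
    """
    features = np.asarray(train_features, dtype=float)
    targets = np.asarray(train_targets, dtype=float)
    if len(features) < 20:
        raise FitrankError("regressor fitting needs at least 20 training rows")
    if spec.search_budget < 1:
        raise FitrankError("search budget must be at least 1")
    rng = np.random.default_rng(seed)
    n = len(features)
    n_val = max(2, int(np.floor(spec.validation_fraction * n + 0.5)))
    order = rng.permutation(n)
    val_idx, fit_idx = order[:n_val], order[n_val:]

    best: tuple[float, dict[str, int]] | None = None
    best_report = None
    for _ in range(spec.search_budget):
        params = {
            "n_estimators": int(
                rng.integers(spec.n_estimators_range[0], spec.n_estimators_range[1] + 1)
            ),
            "max_depth": int(
                rng.integers(spec.max_depth_range[0], spec.max_depth_range[1] + 1)
            ),
        }
        model = RandomForestRegressor(random_state=seed, **params)
        model.fit(features[fit_idx], targets[fit_idx])
        report = regression_metrics(targets[val_idx], model.predict(features[val_idx]))
        if best is None or report.mse < best[0]:
            best = (report.mse, params)
            best_report = report
    assert best is not None
    final = RandomForestRegressor(random_state=seed, **best[1])
    final.fit(features, targets)
    return FittedRegressor(final), best[1], best_report


# ---------------------------------------------------------------------------
# Replication harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alternative:
    """One competing configuration: encodings x sampler x combination mode."""

    id: str
    encodings: tuple[str, ...]
    sampler: str = "none"
    combine: str = "single"  # single | concat | vote
    standardize: bool | None = None  # None: standardize unless pure one-hot

    def __post_init__(self) -> None:
        if self.combine not in ("single", "concat", "vote"):
            raise FitrankError(f"unknown combine mode {self.combine!r}")
        if self.combine == "single" and len(self.encodings) != 1:
            raise FitrankError("combine='single' takes exactly one encoding")
        if self.combine == "vote" and len(self.encodings) < 2:
            raise FitrankError("voting needs at least two encodings")


@dataclass
class ReplicateTable:
    """Tidy per-(alternative, seed) metric rows plus any failed cells."""

    frame: pd.DataFrame
    failures: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _should_standardize(alt: Alternative, encoding_names: Sequence[str]) -> bool:
    if alt.standardize is not None:
        return alt.standardize
    return any(name != "onehot" for name in encoding_names)


def _fit_predict_single(
    values: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    sampler: str,
    standardize: bool,
    spec: ClassifierSpec,
    seed: int,
    smote_k: int,
) -> tuple[np.ndarray, np.ndarray]:
    resampled = resample_by_name(
        sampler, values[train_idx], labels[train_idx], seed=seed, k=smote_k
    )
    handle = train_classifier(
        resampled.features,
        resampled.labels,
        ClassifierSpec(
            regularization_strength=spec.regularization_strength,
            max_iterations=spec.max_iterations,
            standardize=standardize,
        ),
        seed=seed,
    )
    return handle.predict(values[test_idx]), handle.predict_proba_positive(values[test_idx])


def run_replicates(
    encodings: Mapping[str, EncodingMatrix],
    labels: np.ndarray,
    alternatives: Sequence[Alternative],
    seeds: Sequence[int],
    split: SplitSpec = SplitSpec(),
    classifier: ClassifierSpec = ClassifierSpec(),
    smote_k: int = 5,
) -> ReplicateTable:
    """Evaluate every alternative over every seed with shared per-seed splits.

    Per seed: one stratified split is drawn and shared by all alternatives
    (paired design); each alternative resamples its own training view, trains,
    and is scored on the identical test set. Failing cells are recorded and
    the run continues.
    """
    labels = np.asarray(labels)
    seeds = list(seeds)
    if len(seeds) < 2:
        raise FitrankError("need at least 2 seeds to estimate dispersion")
    if len(set(seeds)) != len(seeds):
        raise FitrankError("seeds must be unique")
    for alt in alternatives:
        for name in alt.encodings:
            if name not in encodings:
                raise FitrankError(
                    f"alternative {alt.id!r} references unknown encoding {name!r}"
                )
    for name, matrix in encodings.items():
        if matrix.shape[0] != len(labels):
            raise FitrankError(f"encoding {name!r} row count != label count")

    rows: list[dict] = []
    failures: list[tuple[str, int, str]] = []
    for seed in seeds:
        train_idx, test_idx = stratified_split_indices(
            labels, SplitSpec(split.test_fraction, seed=seed, stratified=split.stratified)
        )
        assert len(np.intersect1d(train_idx, test_idx)) == 0  # leakage guard
        for alt in alternatives:
            try:
                if alt.combine == "vote":
                    voter_labels, voter_probs = [], []
                    for name in alt.encodings:
                        pred, prob = _fit_predict_single(
                            encodings[name].values, labels, train_idx, test_idx,
                            alt.sampler, _should_standardize(alt, [name]),
                            classifier, seed, smote_k,
                        )
                        voter_labels.append(pred)
                        voter_probs.append(prob)
                    vote = majority_vote(np.array(voter_labels), np.array(voter_probs))
                    report = classification_metrics(labels[test_idx], vote.labels)
                else:
                    if alt.combine == "concat":
                        matrix = concat_encodings([encodings[n] for n in alt.encodings])
                        values = matrix.values
                    else:
                        values = encodings[alt.encodings[0]].values
                    pred, _ = _fit_predict_single(
                        values, labels, train_idx, test_idx,
                        alt.sampler, _should_standardize(alt, alt.encodings),
                        classifier, seed, smote_k,
                    )
                    report = classification_metrics(labels[test_idx], pred)
                rows.append({"alternative": alt.id, "seed": seed, **report.as_dict()})
            except Exception as exc:  # failed cells are reported, not imputed
                failures.append((alt.id, seed, repr(exc)))
    frame = pd.DataFrame(rows)
    return ReplicateTable(frame=frame, failures=failures)
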