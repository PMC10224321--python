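"""Prevalence-preserving splitting and class rebalancing.

The three rebalancers (undersampling, random oversampling, SMOTE) all return
a :class:`ResampleResult` with exact 1:1 class balance and per-row provenance
tags. SMOTE is implemented from its defining algorithm: each synthetic point
is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``, ``x`` a minority row and
``x_nn`` one of its k nearest minority neighbours under Euclidean distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datatypes import LabeledDataset
from .exceptions import FitrankError, SingleClassError

__all__ = [
    "SplitSpec",
    "ResampleResult",
    "stratified_split_indices",
    "stratified_split",
    "undersample",
    "oversample_random",
    "smote",
    "resample_by_name",
    "SAMPLERS",
]


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise FitrankError(
                f"test_fraction must lie strictly in (0, 1), got {self.test_fraction}"
            )


@dataclass
class ResampleResult:
    features: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray  # per-row tag: original | duplicated | synthetic

    def __post_init__(self) -> None:
        if not (len(self.features) == len(self.labels) == len(self.provenance)):
            raise FitrankError("resample result rows must align")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split_indices(
    labels: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Split row indices so each class contributes round(test_fraction * size) test rows.

    With ``stratified=False`` a single global split of the same size is drawn.
    Index arrays are returned sorted; two calls with the same spec are identical.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    classes = np.unique(labels)
    if spec.stratified:
        if len(classes) < 2:
            raise SingleClassError("stratified split requires both classes present")
        test_parts, train_parts = [], []
        for value in classes:
            idx = np.flatnonzero(labels == value)
            if len(idx) < 2:
                raise FitrankError(
                    f"class {value!r} has fewer than 2 members; cannot split"
                )
            n_test = _round_half_up(spec.test_fraction * len(idx))
            if n_test < 1 or n_test >= len(idx):
                raise FitrankError(
                    f"test_fraction {spec.test_fraction} leaves class {value!r} empty "
                    "on one side of the split"
                )
            shuffled = rng.permutation(idx)
            test_parts.append(shuffled[:n_test])
            train_parts.append(shuffled[n_test:])
        test_idx = np.sort(np.concatenate(test_parts))
        train_idx = np.sort(np.concatenate(train_parts))
    else:
        n = len(labels)
        n_test = _round_half_up(spec.test_fraction * n)
        if n_test < 1 or n_test >= n:
            raise FitrankError("split leaves one side empty")
        shuffled = rng.permutation(n)
        test_idx = np.sort(shuffled[:n_test])
        train_idx = np.sort(shuffled[n_test:])
    return train_idx, test_idx


def stratified_split(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split a labeled dataset into disjoint, exhaustive train/test subsets."""
    train_idx, test_idx = stratified_split_indices(dataset.labels, spec)
    return dataset.subset(train_idx), dataset.subset(test_idx)


def _split_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (minority indices, majority indices); ties count as balanced."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise SingleClassError(
            f"rebalancing requires exactly 2 classes, got {len(classes)}"
        )
    minority = classes[np.argmin(counts)]
    return np.flatnonzero(labels == minority), np.flatnonzero(labels != minority)


def undersample(features: np.ndarray, labels: np.ndarray, seed: int = 0) -> ResampleResult:
    """Randomly reduce the majority class (without replacement) to minority size."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    min_idx, maj_idx = _split_classes(labels)
    if len(min_idx) == len(maj_idx):
        keep = np.arange(len(labels))
    else:
        rng = np.random.default_rng(seed)
        kept_maj = rng.choice(maj_idx, size=len(min_idx), replace=False)
        keep = np.sort(np.concatenate([min_idx, kept_maj]))
    return ResampleResult(
        features=features[keep],
        labels=labels[keep],
        provenance=np.full(len(keep), "original", dtype=object),
    )


def oversample_random(
    features: np.ndarray, labels: np.ndarray, seed: int = 0
) -> ResampleResult:
    """Duplicate random minority rows (with replacement) until classes balance."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    min_idx, maj_idx = _split_classes(labels)
    n_extra = len(maj_idx) - len(min_idx)
    if n_extra == 0:
        extra = np.array([], dtype=int)
    else:
        rng = np.random.default_rng(seed)
        extra = rng.choice(min_idx, size=n_extra, replace=True)
    provenance = np.concatenate(
        [
            np.full(len(labels), "original", dtype=object),
            np.full(len(extra), "duplicated", dtype=object),
        ]
    )
    return ResampleResult(
        features=np.vstack([features, features[extra]]) if len(extra) else features.copy(),
        labels=np.concatenate([labels, labels[extra]]) if len(extra) else labels.copy(),
        provenance=provenance,
    )


def smote(
    features: np.ndarray, labels: np.ndarray, k: int = 5, seed: int = 0
) -> ResampleResult:
    """Balance classes by interpolating synthetic minority points.

    ``k`` is clipped to ``n_minority - 1``. A single-member minority class
    falls back to duplication with a warning.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if k < 1:
        raise FitrankError("k must be at least 1")
    min_idx, maj_idx = _split_classes(labels)
    n_new = len(maj_idx) - len(min_idx)
    if n_new == 0:
        return ResampleResult(
            features=features.copy(),
            labels=labels.copy(),
            provenance=np.full(len(labels), "original", dtype=object),
        )
    rng = np.random.default_rng(seed)
    minority = features[min_idx]
    if len(min_idx) == 1:
        warnings.warn(
            "minority class has a single member; SMOTE falls back to duplication",
            stacklevel=2,
        )
        new_rows = np.repeat(minority, n_new, axis=0)
        tag = "duplicated"
    else:
        k_eff = min(k, len(min_idx) - 1)
        distances = cdist(minority, minority)
        np.fill_diagonal(distances, np.inf)
        neighbors = np.argsort(distances, axis=1, kind="stable")[:, :k_eff]
        new_rows = np.empty((n_new, features.shape[1]))
        for row in range(n_new):
            i = int(rng.integers(len(min_idx)))
            j = int(neighbors[i, rng.integers(k_eff)])
            u = rng.random()
            new_rows[row] = minority[i] + u * (minority[j] - minority[i])
        tag = "synthetic"
    minority_label = labels[min_idx[0]]
    provenance = np.concatenate(
        [
            np.full(len(labels), "original", dtype=object),
            np.full(n_new, tag, dtype=object),
        ]
    )
    return ResampleResult(
        features=np.vstack([features, new_rows]),
        labels=np.concatenate([labels, np.full(n_new, minority_label, dtype=labels.dtype)]),
        provenance=provenance,
    )


def _identity(features: np.ndarray, labels: np.ndarray, seed: int = 0) -> ResampleResult:
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    return ResampleResult(
        features=features.copy(),
        labels=labels.copy(),
        provenance=np.full(len(labels), "original", dtype=object),
    )


SAMPLERS = {
    "none": _identity,
    "under": undersample,
    "over": oversample_random,
    "smote": smote,
}


def resample_by_name(
    name: str, features: np.ndarray, labels: np.ndarray, seed: int = 0, k: int = 5
) -> ResampleResult:
    """Dispatch a rebalancer by config name (none / under / over / smote)."""
    if name not in SAMPLERS:
        raise FitrankError(f"unknown sampler {name!r}; options: {sorted(SAMPLERS)}")
    if name == "smote":
        return smote(features, labels, k=k, seed=seed)
    return SAMPLERS[name](features, labels, seed=seed)
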