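"""Multi-criteria ranking: entropy weighting and TOPSIS.

Alternatives (encoding x sampler cells, ensembles) are scored on seed-mean
values of the six classification criteria in the fixed order
``(F1, FPR, TPR, precision, NPV, FDR)`` with orientation signs
``(+1, -1, +1, +1, +1, -1)``.

Objective weights come from Shannon entropy of the column-sum-normalised
matrix: ``r_ij = x_ij / sum_i x_ij``; ``E_j = -k * sum_i r_ij ln r_ij`` with
``k = 1 / ln(n)`` and ``0 ln 0 := 0``; ``w_j = (1 - E_j) / sum_j (1 - E_j)``.

The TOPSIS distance stage uses the standard vector normalisation
``v_ij = x_ij / sqrt(sum_i x_ij^2)`` (configurable to sum normalisation),
ideal/anti-ideal per-column extremes oriented by the signs, Euclidean
distances, and closeness ``C_i = d- / (d+ + d-)``, ranked descending.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateMatrixError, FitrankError, MissingCellsError
from .metrics import CRITERIA
from .modeling import ReplicateTable

__all__ = [
    "DecisionMatrix",
    "WeightVector",
    "RankingResult",
    "DEFAULT_SIGNS",
    "build_decision_matrix",
    "entropy_weights",
    "subjective_weights",
    "topsis_rank",
]

#: Orientation for the default criteria: +1 maximise, -1 minimise.
DEFAULT_SIGNS = (1, -1, 1, 1, 1, -1)


@dataclass
class DecisionMatrix:
    x: np.ndarray  # n_alternatives x m_criteria, nonnegative
    alternative_ids: list[str]
    criterion_names: list[str] = field(default_factory=lambda: list(CRITERIA))
    signs: tuple[int, ...] = DEFAULT_SIGNS

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise FitrankError("decision matrix must be 2-D")
        n, m = self.x.shape
        if len(self.alternative_ids) != n:
            raise FitrankError("alternative_ids length mismatch")
        if len(self.criterion_names) != m or len(self.signs) != m:
            raise FitrankError("criterion_names/signs length mismatch")
        if not all(s in (-1, 1) for s in self.signs):
            raise FitrankError("signs must be +1 or -1")
        if not np.all(np.isfinite(self.x)):
            raise FitrankError("decision matrix contains non-finite entries")
        if np.any(self.x < 0):
            raise FitrankError("decision matrix entries must be nonnegative")
        if np.any(self.x.sum(axis=0) <= 0):
            raise DegenerateMatrixError("every criterion column must have positive sum")

    @property
    def n_alternatives(self) -> int:
        return self.x.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.x, columns=self.criterion_names)
        frame.insert(0, "alternative", self.alternative_ids)
        return frame


@dataclass
class WeightVector:
    w: np.ndarray
    method: str  # entropy | subjective

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise FitrankError("weights must be nonnegative")
        if not np.isclose(self.w.sum(), 1.0):
            raise FitrankError(f"weights must sum to 1, got {self.w.sum()}")


@dataclass
class RankingResult:
    alternative_ids: list[str]
    closeness: np.ndarray  # C_i in [0, 1]
    ranks: np.ndarray  # 1 = best
    weights_used: WeightVector

    def to_dict(self) -> dict:
        return {
            "weights_method": self.weights_used.method,
            "weights": {c: float(w) for c, w in zip(CRITERIA, self.weights_used.w)},
            "alternatives": [
                {"alternative": a, "closeness": float(c), "rank": int(r)}
                for a, c, r in zip(self.alternative_ids, self.closeness, self.ranks)
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def build_decision_matrix(replicates: ReplicateTable | pd.DataFrame) -> DecisionMatrix:
    """Aggregate a replicate table into per-alternative seed-mean criterion scores.

    Requires every alternative to carry the identical full seed set and at
    least two seeds; missing cells are reported explicitly.
    """
    frame = replicates.frame if isinstance(replicates, ReplicateTable) else replicates
    required = {"alternative", "seed", *CRITERIA}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise FitrankError(f"replicate table missing columns: {sorted(missing_cols)}")
    all_seeds = sorted(frame["seed"].unique())
    if len(all_seeds) < 2:
        raise MissingCellsError("need at least 2 seeds to build a decision matrix")
    alternatives = sorted(frame["alternative"].unique())
    missing_cells = [
        (alt, seed)
        for alt in alternatives
        for seed in all_seeds
        if not ((frame["alternative"] == alt) & (frame["seed"] == seed)).any()
    ]
    if missing_cells:
        raise MissingCellsError(f"missing (alternative, seed) cells: {missing_cells}")
    sub = frame[["alternative", *CRITERIA]]
    if sub[list(CRITERIA)].isna().any().any():
        bad = sub[sub[list(CRITERIA)].isna().any(axis=1)]["alternative"].unique()
        raise MissingCellsError(
            f"undefined criterion values for alternatives: {sorted(bad)}"
        )
    means = sub.groupby("alternative", sort=True).mean()
    return DecisionMatrix(
        x=means.loc[alternatives, list(CRITERIA)].to_numpy(),
        alternative_ids=alternatives,
    )


def entropy_weights(matrix: DecisionMatrix) -> WeightVector:
    """Objective criterion weights from Shannon entropy of the decision matrix."""
    x = matrix.x
    n = matrix.n_alternatives
    if n < 2:
        raise FitrankError("entropy weighting needs at least 2 alternatives")
    r = x / x.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(r > 0, r * np.log(r), 0.0)
    entropy = -terms.sum(axis=0) / np.log(n)
    divergence = np.clip(1.0 - entropy, 0.0, None)  # clip fp noise below zero
    total = divergence.sum()
    if total <= 1e-12:
        raise DegenerateMatrixError(
            "all criteria are uniform across alternatives; entropy weights undefined"
        )
    return WeightVector(w=divergence / total, method="entropy")


def subjective_weights(
    emphasis: Mapping[str, float] | None = None,
) -> WeightVector:
    """Decision-maker weights, normalised to sum 1.

    The default emphasis (precision 0.20, FPR 0.20, all others 0.15) slightly
    prioritises identifying positives; it is this package's declared default,
    not a value taken from any external study.
    """
    weights = {name: 0.15 for name in CRITERIA}
    weights["precision"] = 0.20
    weights["FPR"] = 0.20
    if emphasis is not None:
        unknown = set(emphasis) - set(CRITERIA)
        if unknown:
            raise FitrankError(f"unknown criteria in emphasis map: {sorted(unknown)}")
        weights = dict(emphasis) if set(emphasis) == set(CRITERIA) else {**weights, **emphasis}
    values = np.array([weights[name] for name in CRITERIA], dtype=float)
    if np.any(values < 0):
        raise FitrankError("subjective weights must be nonnegative")
    if values.sum() <= 0:
        raise FitrankError("subjective weights must not all be zero")
    return WeightVector(w=values / values.sum(), method="subjective")


def topsis_rank(
    matrix: DecisionMatrix,
    weights: WeightVector,
    normalization: str = "vector",
) -> RankingResult:
    """Rank alternatives by closeness to the ideal solution.

    Ties in closeness are broken by alternative id (stable, ascending).
    """
    if len(weights.w) != matrix.x.shape[1]:
        raise FitrankError("weight vector length must equal the criterion count")
    x = matrix.x
    if normalization == "vector":
        norms = np.sqrt((x**2).sum(axis=0))
    elif normalization == "sum":
        norms = x.sum(axis=0)
    else:
        raise FitrankError(f"unknown normalization {normalization!r}")
    v = (x / norms) * weights.w

    signs = np.array(matrix.signs)
    col_max, col_min = v.max(axis=0), v.min(axis=0)
    ideal = np.where(signs == 1, col_max, col_min)
    anti_ideal = np.where(signs == 1, col_min, col_max)
    d_pos = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_neg = np.sqrt(((v - anti_ideal) ** 2).sum(axis=1))
    denom = d_pos + d_neg
    if np.all(denom == 0):
        raise DegenerateMatrixError("all alternatives are identical; TOPSIS undefined")
    closeness = d_neg / denom

    order = sorted(
        range(len(closeness)),
        key=lambda i: (-closeness[i], matrix.alternative_ids[i]),
    )
    ranks = np.empty(len(order), dtype=int)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return RankingResult(
        alternative_ids=list(matrix.alternative_ids),
        closeness=closeness,
        ranks=ranks,
        weights_used=weights,
    )
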