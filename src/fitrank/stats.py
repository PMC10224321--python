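"""Significance machinery: one-way ANOVA, Bonferroni, Tukey HSD, MANOVA.

Established routines back the contracts (scipy's F test and studentized-range
Tukey HSD, statsmodels' MANOVA); the guards, the pairwise-decision layout,
and the calibration tests are owned here. The family-wise level is
``alpha = 0.05`` unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.multivariate.manova import MANOVA

from .exceptions import FitrankError, UndefinedStatisticError

__all__ = [
    "PairwiseDecision",
    "anova_oneway",
    "bonferroni_adjust",
    "tukey_hsd",
    "tukey_table",
    "manova_pillai",
]

GroupedScores = Mapping[str, np.ndarray]


@dataclass(frozen=True)
class PairwiseDecision:
    group_a: str
    group_b: str
    metric: str
    mean_a: float
    mean_b: float
    mean_difference: float
    p_adjusted: float
    reject: bool


def _validate_groups(groups: GroupedScores) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise FitrankError("need at least 2 groups")
    clean: dict[str, np.ndarray] = {}
    for name in sorted(groups):
        values = np.asarray(groups[name], dtype=float)
        if values.ndim != 1 or len(values) < 2:
            raise FitrankError(
                f"group {name!r} must be a 1-D vector with at least 2 observations"
            )
        clean[name] = values
    return clean


def anova_oneway(groups: GroupedScores) -> tuple[float, float]:
    """Classical one-way F test. Returns (F statistic, p-value)."""
    clean = _validate_groups(groups)
    if all(np.var(v) == 0 for v in clean.values()):
        raise UndefinedStatisticError(
            "zero within-group variance in every group; F is undefined"
        )
    f_stat, p_value = sps.f_oneway(*clean.values())
    return float(f_stat), float(p_value)


def bonferroni_adjust(p_values) -> np.ndarray:
    """Multiply by the comparison count and clip at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise FitrankError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def tukey_hsd(
    groups: GroupedScores, alpha: float = 0.05, metric: str = ""
) -> list[PairwiseDecision]:
    """Studentized-range pairwise comparisons at family-wise level alpha."""
    clean = _validate_groups(groups)
    if all(np.var(v) == 0 for v in clean.values()):
        raise UndefinedStatisticError(
            "zero within-group variance in every group; Tukey HSD is undefined"
        )
    names = list(clean)
    result = sps.tukey_hsd(*clean.values())
    decisions = []
    for i, j in combinations(range(len(names)), 2):
        p_adj = float(result.pvalue[i, j])
        mean_a = float(np.mean(clean[names[i]]))
        mean_b = float(np.mean(clean[names[j]]))
        decisions.append(
            PairwiseDecision(
                group_a=names[i],
                group_b=names[j],
                metric=metric,
                mean_a=mean_a,
                mean_b=mean_b,
                mean_difference=mean_a - mean_b,
                p_adjusted=p_adj,
                reject=p_adj < alpha,
            )
        )
    return decisions


def tukey_table(
    scores_by_metric: Mapping[str, GroupedScores], alpha: float = 0.05
) -> pd.DataFrame:
    """One Tukey decision per group pair per metric, as a tidy frame."""
    rows = []
    for metric, groups in scores_by_metric.items():
        for decision in tukey_hsd(groups, alpha=alpha, metric=metric):
            rows.append(
                {
                    "group_a": decision.group_a,
                    "group_b": decision.group_b,
                    "metric": decision.metric,
                    "mean_a": decision.mean_a,
                    "mean_b": decision.mean_b,
                    "mean_difference": decision.mean_difference,
                    "p_adjusted": decision.p_adjusted,
                    "reject": decision.reject,
                }
            )
    return pd.DataFrame(rows)


def manova_pillai(groups: Mapping[str, np.ndarray]) -> tuple[float, float]:
    """Pillai-trace MANOVA across all criteria jointly.

    ``groups`` maps group id to an observations x criteria matrix. Returns
    (Pillai trace, p-value). Raises on singular within-group covariance with
    a hint to drop redundant criteria.
    """
    if len(groups) < 2:
        raise FitrankError("need at least 2 groups")
    blocks, labels = [], []
    m = None
    for name in sorted(groups):
        values = np.asarray(groups[name], dtype=float)
        if values.ndim != 2:
            raise FitrankError(f"group {name!r} must be an observations x criteria matrix")
        if m is None:
            m = values.shape[1]
        elif values.shape[1] != m:
            raise FitrankError("all groups must share the criterion count")
        blocks.append(values)
        labels.extend([name] * len(values))
    assert m is not None
    total = sum(len(b) for b in blocks)
    if total < m + len(groups):
        raise FitrankError(
            f"need at least criteria + groups = {m + len(groups)} observations, got {total}"
        )
    data = pd.DataFrame(np.vstack(blocks), columns=[f"y{j}" for j in range(m)])
    data["group"] = labels
    formula = " + ".join(data.columns[:-1]) + " ~ C(group)"
    try:
        fit = MANOVA.from_formula(formula, data=data)
        table = fit.mv_test().results["C(group)"]["stat"]
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise UndefinedStatisticError(
            "MANOVA failed (likely singular within-group covariance); "
            "consider removing collinear criteria"
        ) from exc
    pillai = float(table.loc["Pillai's trace", "Value"])
    p_value = float(table.loc["Pillai's trace", "Pr > F"])
    if not np.isfinite(p_value):
        raise UndefinedStatisticError("MANOVA p-value is not finite")
    return pillai, p_value
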