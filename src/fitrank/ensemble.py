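"""Combining encodings: feature-axis concatenation and majority voting.

"Combining by adding together" is realised as concatenation along the feature
axis — the encoder widths (20 / 20·L / embedding dimension) cannot be summed
elementwise. Majority voting takes a strict majority of per-voter labels;
ties (possible only with an even voter count) are broken by the mean positive
class probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import EncodingMatrix
from .exceptions import FitrankError

__all__ = ["VoteResult", "concat_encodings", "majority_vote"]


@dataclass
class VoteResult:
    labels: np.ndarray
    per_voter_labels: np.ndarray  # voters x samples
    tie_broken: np.ndarray  # bool per sample


def concat_encodings(matrices: Sequence[EncodingMatrix]) -> EncodingMatrix:
    """Concatenate encodings along the feature axis; blocks stay sliceable.

    Duplicate feature names across blocks are suffixed with the block index.
    Row counts and row order must match exactly.
    """
    if not matrices:
        raise FitrankError("need at least one encoding matrix")
    if len(matrices) == 1:
        return matrices[0]
    first = matrices[0]
    for m in matrices[1:]:
        if m.shape[0] != first.shape[0]:
            raise FitrankError(
                f"row-count mismatch: {first.shape[0]} vs {m.shape[0]}"
            )
        if m.row_ids != first.row_ids:
            raise FitrankError("row order differs between encodings")

    seen: set[str] = set()
    names: list[str] = []
    for block, m in enumerate(matrices):
        for name in m.feature_names:
            if name in seen:
                name = f"{name}__{block}"
            seen.add(name)
            names.append(name)
    return EncodingMatrix(
        encoding_name="+".join(m.encoding_name for m in matrices),
        values=np.hstack([m.values for m in matrices]),
        feature_names=names,
        row_ids=list(first.row_ids),
    )


def majority_vote(
    per_voter_labels, per_voter_probabilities
) -> VoteResult:
    """Column-wise strict-majority vote over binary voter predictions.

    ``per_voter_labels`` and ``per_voter_probabilities`` are voters x samples;
    probabilities are positive-class probabilities used only to break ties
    (mean >= 0.5 votes positive).
    """
    votes = np.asarray(per_voter_labels)
    probs = np.asarray(per_voter_probabilities, dtype=float)
    if votes.ndim != 2:
        raise FitrankError("per-voter labels must be a voters x samples matrix")
    if votes.shape[0] == 0:
        raise FitrankError("majority vote needs at least one voter")
    if probs.shape != votes.shape:
        raise FitrankError(
            f"probability matrix shape {probs.shape} != label matrix shape {votes.shape}"
        )
    if not np.isin(votes, (0, 1)).all():
        raise FitrankError("voter labels must be binary 0/1")

    n_pos = votes.sum(axis=0)
    n_neg = votes.shape[0] - n_pos
    tie = n_pos == n_neg
    labels = (n_pos > n_neg).astype(int)
    labels[tie] = (probs.mean(axis=0)[tie] >= 0.5).astype(int)
    return VoteResult(labels=labels, per_voter_labels=votes, tie_broken=tie)
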