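"""Core data containers shared across pipeline stages.

All containers are plain dataclasses around numpy/pandas structures and
validate their invariants at construction time. Random number generation
throughout the package uses :func:`numpy.random.default_rng` (PCG64), so
identical seeds give identical outputs across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import FitrankError

#: Canonical amino-acid one-letter codes in fixed alphabetical channel order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Recognised sequencing pools.
POOLS = ("naive", "MACS", "FACS")


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence with identity, source pool, and read counts."""

    id: str
    sequence: str
    pool: str = "naive"
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pool not in POOLS:
            raise FitrankError(f"unknown pool {self.pool!r}; expected one of {POOLS}")


@dataclass
class ReadCountTable:
    """Per-pool mapping sequence -> nonnegative read count.

    Sequences may be deliberately invalid amino-acid strings so that the
    cleaning stage can be exercised on simulated data.
    """

    pool: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.pool not in POOLS:
            raise FitrankError(f"unknown pool {self.pool!r}; expected one of {POOLS}")
        for seq, count in self.counts.items():
            if count < 0:
                raise FitrankError(f"negative count {count} for sequence {seq!r}")

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items())
        return pd.DataFrame(rows, columns=["sequence", "count"]).assign(pool=self.pool)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, pool: str | None = None) -> "ReadCountTable":
        pool = pool if pool is not None else str(frame["pool"].iloc[0])
        counts = {str(s): int(c) for s, c in zip(frame["sequence"], frame["count"])}
        return cls(pool=pool, counts=counts)


@dataclass
class LabeledDataset:
    """Matched sequences and labels (binary fitness classes or Tm values)."""

    ids: list[str]
    sequences: list[str]
    labels: np.ndarray
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not (len(self.ids) == len(self.sequences) == len(self.labels)):
            raise FitrankError(
                "ids, sequences and labels must align: "
                f"{len(self.ids)} / {len(self.sequences)} / {len(self.labels)}"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels == 1))

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        idx = list(indices)
        return LabeledDataset(
            ids=[self.ids[i] for i in idx],
            sequences=[self.sequences[i] for i in idx],
            labels=self.labels[idx],
            source=self.source,
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "sequence": self.sequences, "label": self.labels}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, source: str = "") -> "LabeledDataset":
        ids = [str(x) for x in frame["id"]] if "id" in frame else [
            f"seq_{i:06d}" for i in range(len(frame))
        ]
        return cls(
            ids=ids,
            sequences=[str(s) for s in frame["sequence"]],
            labels=frame["label"].to_numpy(),
            source=source,
        )


@dataclass
class StabilityTable:
    """Variable-length protein records with per-record pH and melting temperature."""

    frame: pd.DataFrame  # columns: sequence, ph, tm

    def __post_init__(self) -> None:
        missing = {"sequence", "ph", "tm"} - set(self.frame.columns)
        if missing:
            raise FitrankError(f"stability table missing columns: {sorted(missing)}")
        if not np.all(np.isfinite(self.frame["tm"].to_numpy(dtype=float))):
            raise FitrankError("stability table contains non-finite Tm values")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class EncodingMatrix:
    """Numeric feature matrix for one named encoding, rows aligned to input order."""

    encoding_name: str
    values: np.ndarray
    feature_names: list[str]
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FitrankError("encoding values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.row_ids) != n:
            raise FitrankError(f"row_ids length {len(self.row_ids)} != n rows {n}")
        if len(self.feature_names) != m:
            raise FitrankError(
                f"feature_names length {len(self.feature_names)} != n features {m}"
            )
        if len(set(self.feature_names)) != m:
            raise FitrankError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise FitrankError("encoding matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, "id", self.row_ids)
        return frame
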