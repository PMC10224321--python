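"""Sequence cleaning, enrichment frequency filtering, pool merging, and labeling.

The enrichment pipeline turns raw per-pool read-count tables into a binary
labeled dataset:

1. drop sequences containing stop codons (``*``) or non-canonical characters;
2. drop sub-threshold background reads (keep count >= 10 in MACS, >= 4 in FACS);
3. label the MACS/FACS union positive; label naive-pool sequences negative
   unless they appear in the enriched union or sit within hamming distance 1
   of any enriched sequence (purged as likely sequencing errors).

Stability tables are filtered to one pH and binarised by two Tm thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .datatypes import AA_ALPHABET, LabeledDataset, ReadCountTable, StabilityTable
from .exceptions import (
    FitrankError,
    InvalidThresholdError,
    LengthMismatchError,
    UnsupportedPoolError,
)

__all__ = [
    "CleaningReport",
    "clean_sequences",
    "clean_table",
    "frequency_filter",
    "hamming",
    "build_labeled_dataset",
    "filter_ph",
    "filter_stability",
    "KEEP_THRESHOLDS",
]

_VALID = frozenset(AA_ALPHABET)

#: Minimum read count a sequence must reach to be kept, per enrichment pool.
KEEP_THRESHOLDS = {"MACS": 10, "FACS": 4}


@dataclass(frozen=True)
class CleaningReport:
    n_input: int
    n_removed_stop: int
    n_removed_invalid: int
    n_kept: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_kept + self.n_removed_stop + self.n_removed_invalid:
            raise FitrankError("cleaning report counts do not add up")

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_removed_stop": self.n_removed_stop,
            "n_removed_invalid": self.n_removed_invalid,
            "n_kept": self.n_kept,
        }


def clean_sequences(raw: Iterable[str]) -> tuple[list[str], CleaningReport]:
    """Keep only strings over the 20 canonical codes, preserving input order.

    Sequences containing ``*`` count as stop-codon removals; any other
    non-canonical character counts as invalid.
    """
    kept: list[str] = []
    n_stop = n_invalid = 0
    raw = list(raw)
    for seq in raw:
        if "*" in seq:
            n_stop += 1
        elif set(seq) - _VALID:
            n_invalid += 1
        else:
            kept.append(seq)
    report = CleaningReport(
        n_input=len(raw),
        n_removed_stop=n_stop,
        n_removed_invalid=n_invalid,
        n_kept=len(kept),
    )
    return kept, report


def clean_table(table: ReadCountTable) -> tuple[ReadCountTable, CleaningReport]:
    """Apply :func:`clean_sequences` to the keys of a read-count table."""
    kept, report = clean_sequences(sorted(table.counts))
    counts = {seq: table.counts[seq] for seq in kept}
    return ReadCountTable(pool=table.pool, counts=counts), report


def frequency_filter(table: ReadCountTable) -> set[str]:
    """Return sequences at or above the keep threshold for the table's pool."""
    if table.pool not in KEEP_THRESHOLDS:
        raise UnsupportedPoolError(
            f"frequency filtering is defined for pools {sorted(KEEP_THRESHOLDS)}, "
            f"not {table.pool!r}"
        )
    threshold = KEEP_THRESHOLDS[table.pool]
    return {seq for seq, count in table.counts.items() if count >= threshold}


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise LengthMismatchError(
            f"hamming distance undefined for lengths {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def _masked_patterns(seq: str) -> set[str]:
    """One-position-masked variants; two equal-length strings are at hamming
    distance <= 1 iff they are equal or share such a pattern."""
    return {seq[:i] + "\0" + seq[i + 1 :] for i in range(len(seq))}


def _one_neighbor_patterns(sequences: Iterable[str]) -> set[str]:
    out: set[str] = set()
    for seq in sequences:
        out |= _masked_patterns(seq)
    return out


def build_labeled_dataset(
    naive: Iterable[str],
    macs_kept: Iterable[str],
    facs_kept: Iterable[str],
    source: str = "affibody",
) -> LabeledDataset:
    """Merge enrichment pools into positives and purge near-miss naive negatives.

    Positives are the MACS/FACS union. Negatives are naive sequences that are
    not enriched and lie at hamming distance >= 2 from every enriched
    sequence; only the naive pool is ever purged. Purge bookkeeping is stored
    in ``meta`` (``n_naive``, ``n_overlap``, ``n_purged``).
    """
    naive_set = set(naive)
    enriched = set(macs_kept) | set(facs_kept)

    if enriched:
        lengths = {len(s) for s in enriched} | {len(s) for s in naive_set}
        if len(lengths) > 1:
            raise LengthMismatchError(
                f"pools mix sequence lengths {sorted(lengths)}; hamming purge undefined"
            )
        near = _one_neighbor_patterns(enriched)
    else:
        near = set()

    overlap = naive_set & enriched
    negatives = sorted(
        s
        for s in naive_set
        if s not in enriched and (not near or near.isdisjoint(_masked_patterns(s)))
    )
    n_purged = len(naive_set) - len(overlap) - len(negatives)

    positives = sorted(enriched)
    ids = [f"enriched_{i:06d}" for i in range(len(positives))] + [
        f"naive_{i:06d}" for i in range(len(negatives))
    ]
    labels = np.concatenate(
        [np.ones(len(positives), dtype=int), np.zeros(len(negatives), dtype=int)]
    )
    return LabeledDataset(
        ids=ids,
        sequences=positives + negatives,
        labels=labels,
        source=source,
        meta={
            "n_naive": len(naive_set),
            "n_overlap": len(overlap),
            "n_purged": n_purged,
        },
    )


def filter_ph(table: StabilityTable, ph: float = 7.0) -> StabilityTable:
    """Keep only records characterised at the given pH (used for regression)."""
    frame = table.frame[table.frame["ph"] == ph].reset_index(drop=True)
    return StabilityTable(frame=frame)


def filter_stability(
    table: StabilityTable,
    ph: float = 7.0,
    low_max: float = 35.0,
    high_min: float = 60.0,
) -> LabeledDataset:
    """Binarise a stability table at one pH into low (Tm <= low_max) vs high (Tm >= high_min).

    Records with Tm strictly between the thresholds are excluded from the
    classification dataset (use :func:`filter_ph` to retain them for
    regression).
    """
    if low_max >= high_min:
        raise InvalidThresholdError(
            f"low_max ({low_max}) must be strictly below high_min ({high_min})"
        )
    frame = filter_ph(table, ph).frame
    tm = frame["tm"].to_numpy(dtype=float)
    is_low = tm <= low_max
    is_high = tm >= high_min
    keep = is_low | is_high
    kept = frame[keep].reset_index(drop=True)
    labels = is_high[keep].astype(int)
    return LabeledDataset(
        ids=[f"nesp_{i:06d}" for i in kept.index],
        sequences=[str(s) for s in kept["sequence"]],
        labels=labels,
        source="stability",
        meta={"ph": ph, "low_max": low_max, "high_min": high_min,
              "n_excluded_between": int(len(frame) - keep.sum())},
    )
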