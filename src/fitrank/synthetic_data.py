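"""Synthetic enrichment experiments and stability tables with known ground truth.

Two generators are provided so every downstream stage is testable without
external data:

* an affibody-like library of fixed-length 58-aa sequences mutated at a small
  set of variable positions, with a planted fitness signal (logistic in mean
  Eisenberg hydrophobicity over the variable positions, optionally with a
  pairwise epistatic term), plus MACS/FACS/naive read-count tables containing
  sub-threshold background reads and deliberate one-hamming near-misses;
* a table of variable-length proteins with per-record pH and melting
  temperature generated by an additive model.

All randomness flows through ``numpy.random.default_rng`` (PCG64); identical
configurations and seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import AA_ALPHABET, LabeledDataset, ReadCountTable, StabilityTable
from .encoders import EISENBERG, HYDROPHOBIC_SET
from .exceptions import DegenerateLibraryError, FitrankError, InvalidConfigError

__all__ = [
    "AffibodySimConfig",
    "NespSimConfig",
    "simulate_affibody_library",
    "simulate_enrichment_reads",
    "simulate_nesp_like",
    "DEFAULT_SCAFFOLD",
]

#: 58-residue Z-domain scaffold used as the default library backbone.
DEFAULT_SCAFFOLD = "VDNKFNKEQQNAFYEILHLPNLNEEQRNAFIQSLKDDPSQSANLLAEAKKLNDAQAPK"

#: Default randomised positions (13 sites on the first two helices, 0-based).
DEFAULT_VARIABLE_POSITIONS = frozenset({8, 9, 10, 12, 13, 16, 17, 23, 24, 27, 31, 32, 34})

SIGNAL_MODELS = ("hydrophobicity-linear", "pairwise-epistatic")


@dataclass(frozen=True)
class AffibodySimConfig:
    scaffold: str = DEFAULT_SCAFFOLD
    variable_positions: frozenset[int] = DEFAULT_VARIABLE_POSITIONS
    n_unique: int = 1000
    prevalence: float = 0.07
    signal_model: str = "hydrophobicity-linear"
    signal_slope: float = 100.0
    epistasis_pairs: int = 3
    epistasis_weight: float = 1.0
    noise_background: float = 25.0
    n_invalid: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.scaffold) != 58:
            raise InvalidConfigError(
                f"scaffold must be 58 residues, got {len(self.scaffold)}"
            )
        positions = frozenset(int(p) for p in self.variable_positions)
        object.__setattr__(self, "variable_positions", positions)
        if len(positions) > 17:
            raise InvalidConfigError(
                f"at most 17 variable positions allowed, got {len(positions)}"
            )
        if positions and not all(0 <= p < 58 for p in positions):
            raise InvalidConfigError("variable positions must lie in [0, 58)")
        if self.n_unique < 10:
            raise InvalidConfigError("n_unique must be at least 10")
        if not 0.0 < self.prevalence < 1.0:
            raise InvalidConfigError("prevalence must lie strictly in (0, 1)")
        if self.signal_model not in SIGNAL_MODELS:
            raise InvalidConfigError(
                f"unknown signal model {self.signal_model!r}; options: {SIGNAL_MODELS}"
            )
        if self.noise_background < 0:
            raise InvalidConfigError("noise_background must be nonnegative")


def _fitness_probabilities(
    sequences: list[str], config: AffibodySimConfig, rng: np.random.Generator
) -> np.ndarray:
    positions = sorted(config.variable_positions)
    profile = np.array(
        [[EISENBERG[seq[p]] for p in positions] for seq in sequences]
    )
    score = profile.mean(axis=1)
    if config.signal_model == "pairwise-epistatic" and len(positions) >= 2:
        n_pairs = min(config.epistasis_pairs, len(positions) * (len(positions) - 1) // 2)
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < n_pairs:
            i, j = rng.choice(len(positions), size=2, replace=False)
            chosen.add((min(i, j), max(i, j)))
        for i, j in sorted(chosen):
            score += (
                config.epistasis_weight / len(positions)
            ) * profile[:, i] * profile[:, j]
    # Center the sigmoid at the (1 - prevalence) score quantile so the
    # high-fitness mass matches the requested prevalence; otherwise the
    # positive draw dilutes the planted signal beyond recovery.
    center = np.quantile(score, 1.0 - config.prevalence)
    return expit(config.signal_slope * (score - center))


def simulate_affibody_library(
    config: AffibodySimConfig,
) -> tuple[LabeledDataset, np.ndarray]:
    """Generate a unique-sequence library with planted binary fitness labels.

    Returns the labeled dataset and the per-sequence ground-truth fitness
    probability. Exactly ``floor(prevalence * n_unique)`` sequences are
    labeled positive, drawn without replacement with probability proportional
    to the planted fitness signal.
    """
    positions = sorted(config.variable_positions)
    if not positions:
        raise DegenerateLibraryError(
            "no variable positions: every sequence would equal the scaffold"
        )
    capacity = 20 ** len(positions)
    if config.n_unique > capacity:
        raise InvalidConfigError(
            f"n_unique={config.n_unique} exceeds library capacity {capacity}"
        )
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()
    sequences: list[str] = []
    scaffold = list(config.scaffold)
    while len(sequences) < config.n_unique:
        chars = scaffold.copy()
        for p in positions:
            chars[p] = AA_ALPHABET[rng.integers(20)]
        seq = "".join(chars)
        if seq not in seen:
            seen.add(seq)
            sequences.append(seq)

    probabilities = _fitness_probabilities(sequences, config, rng)
    n_pos = int(np.floor(config.prevalence * config.n_unique + 1e-9))
    n_pos = max(n_pos, 1)
    weights = probabilities / probabilities.sum()
    pos_idx = rng.choice(config.n_unique, size=n_pos, replace=False, p=weights)
    labels = np.zeros(config.n_unique, dtype=int)
    labels[pos_idx] = 1

    dataset = LabeledDataset(
        ids=[f"lib_{i:06d}" for i in range(config.n_unique)],
        sequences=sequences,
        labels=labels,
        source="affibody-sim",
        meta={"seed": config.seed, "signal_model": config.signal_model},
    )
    return dataset, probabilities


def _corrupt(
    seq: str, rng: np.random.Generator, n_sub_range: tuple[int, int] = (1, 3)
) -> str:
    """Apply 1-3 random substitutions, mimicking sequencing error."""
    chars = list(seq)
    n_sub = int(rng.integers(n_sub_range[0], n_sub_range[1] + 1))
    sites = rng.choice(len(chars), size=n_sub, replace=False)
    for site in sites:
        options = [aa for aa in AA_ALPHABET if aa != chars[site]]
        chars[site] = options[rng.integers(len(options))]
    return "".join(chars)


def simulate_enrichment_reads(
    dataset: LabeledDataset, config: AffibodySimConfig
) -> tuple[ReadCountTable, ReadCountTable, ReadCountTable]:
    """Derive naive/MACS/FACS read-count tables from a simulated library.

    Guarantees: every planted positive clears the MACS (>= 10) or FACS (>= 4)
    keep threshold; injected background reads (corrupted copies of library
    members, 1-3 substitutions) stay strictly below the thresholds; for
    libraries of >= 100 sequences at least one naive-only record is planted at
    hamming distance 1 from an enriched sequence to exercise the purge.
    """
    if len(dataset) == 0:
        raise FitrankError("cannot simulate reads for an empty dataset")
    rng = np.random.default_rng((config.seed, 1))
    positives = [s for s, y in zip(dataset.sequences, dataset.labels) if y == 1]
    enriched_set = set(positives)
    library_set = set(dataset.sequences)

    naive_counts: dict[str, int] = {
        seq: int(1 + rng.poisson(5)) for seq in dataset.sequences
    }
    macs_counts: dict[str, int] = {}
    facs_counts: dict[str, int] = {}
    for seq in positives:
        route = int(rng.integers(3))  # 0: MACS, 1: FACS, 2: both
        if route in (0, 2):
            macs_counts[seq] = int(10 + rng.poisson(15))
        if route in (1, 2):
            facs_counts[seq] = int(4 + rng.poisson(8))

    def _fresh_junk() -> str:
        for _ in range(100):
            base = dataset.sequences[rng.integers(len(dataset))]
            junk = _corrupt(base, rng)
            if junk not in enriched_set and junk not in library_set:
                return junk
        raise FitrankError("could not place a background read outside the library")

    for counts, high in ((macs_counts, 9), (facs_counts, 3), (naive_counts, 3)):
        n_junk = int(rng.poisson(config.noise_background))
        for _ in range(n_junk):
            junk = _fresh_junk()
            if junk not in counts:
                counts[junk] = int(rng.integers(1, high + 1))

    if positives:
        n_near = max(1, len(dataset) // 100) if len(dataset) >= 100 else 1
        placed = 0
        attempts = 0
        positions = sorted(config.variable_positions)
        while placed < n_near and attempts < 100 * n_near:
            attempts += 1
            base = positives[rng.integers(len(positives))]
            site = positions[rng.integers(len(positions))]
            options = [aa for aa in AA_ALPHABET if aa != base[site]]
            near = base[:site] + options[rng.integers(len(options))] + base[site + 1 :]
            if near in enriched_set:
                continue
            naive_counts.setdefault(near, int(1 + rng.poisson(2)))
            placed += 1

    for _ in range(config.n_invalid):
        base = dataset.sequences[rng.integers(len(dataset))]
        site = int(rng.integers(len(base)))
        bad_char = "*" if rng.integers(2) == 0 else "X"
        naive_counts[base[:site] + bad_char + base[site + 1 :]] = 1

    return (
        ReadCountTable(pool="naive", counts=naive_counts),
        ReadCountTable(pool="MACS", counts=macs_counts),
        ReadCountTable(pool="FACS", counts=facs_counts),
    )


@dataclass(frozen=True)
class NespSimConfig:
    n_records: int = 500
    length_range: tuple[int, int] = (50, 300)
    ph_values: tuple[float, ...] = (5.0, 6.0, 7.0, 8.0)
    tm_intercept: float = 30.0
    tm_hydrophobic_coeff: float = 60.0
    tm_length_coeff: float = 0.01
    tm_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 2:
            raise InvalidConfigError("minimum sequence length must be at least 2")
        if hi < lo:
            raise InvalidConfigError("length_range must satisfy min <= max")
        if self.n_records < 10:
            raise InvalidConfigError("n_records must be at least 10")
        if not self.ph_values:
            raise InvalidConfigError("ph_values must be non-empty")
        if self.tm_noise_sd < 0:
            raise InvalidConfigError("tm_noise_sd must be nonnegative")


def nesp_tm(sequence: str, config: NespSimConfig) -> float:
    """Noise-free additive melting temperature for one sequence."""
    frac_h = sum(1 for aa in sequence if aa in HYDROPHOBIC_SET) / len(sequence)
    return (
        config.tm_intercept
        + config.tm_hydrophobic_coeff * frac_h
        + config.tm_length_coeff * len(sequence)
    )


def simulate_nesp_like(config: NespSimConfig) -> StabilityTable:
    """Generate variable-length proteins with pH and additive-model Tm labels."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    alphabet = np.array(list(AA_ALPHABET))
    rows = []
    for _ in range(config.n_records):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(alphabet[rng.integers(0, 20, size=length)])
        ph = float(rng.choice(config.ph_values))
        tm = nesp_tm(seq, config) + float(rng.normal(0.0, config.tm_noise_sd)) if config.tm_noise_sd > 0 else nesp_tm(seq, config)
        rows.append((seq, ph, tm))
    frame = pd.DataFrame(rows, columns=["sequence", "ph", "tm"])
    return StabilityTable(frame=frame)


def write_fasta(dataset: LabeledDataset, path: str | Path) -> None:
    """Write dataset sequences as plain FASTA (label carried in the header)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=sid, description=f"label={int(lab)}")
        for sid, seq, lab in zip(dataset.ids, dataset.sequences, dataset.labels)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_count_tables(
    tables: tuple[ReadCountTable, ...], path: str | Path
) -> None:
    """Write read-count tables to one tidy CSV (pool, sequence, count)."""
    frame = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    frame[["pool", "sequence", "count"]].to_csv(path, index=False)


def with_seed(config: AffibodySimConfig, seed: int) -> AffibodySimConfig:
    """Convenience: copy a config with a different seed."""
    return replace(config, seed=seed)
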