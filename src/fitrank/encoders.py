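"""Fixed-size numeric sequence representations.

Three encoder families are provided:

* :func:`encode_onehot` — position x amino-acid indicator matrix (width 20·L);
* :func:`encode_physiochemical` — exactly twenty global descriptors combining
  Biopython ``ProtParam`` quantities with statistics over vendored residue
  scales (Eisenberg consensus hydrophobicity, Kyte–Doolittle hydropathy,
  Boman interaction potential);
* :func:`encode_with_adapter` — pluggable fixed-vector embedding adapters.
  Real protein-language-model adapters can be registered behind the same
  contract; the shipped :class:`HashedKmerAdapter` is a deterministic mock
  (keyed-hash feature hashing of k-mer counts) that needs no model weights.
"""

from __future__ import annotations

import csv
import hashlib
import math
from abc import ABC, abstractmethod
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .datatypes import AA_ALPHABET, EncodingMatrix
from .exceptions import AdapterError, FitrankError, RaggedLengthError

__all__ = [
    "encode_onehot",
    "decode_onehot",
    "encode_physiochemical",
    "encode_with_adapter",
    "encode_by_name",
    "EmbeddingAdapter",
    "HashedKmerAdapter",
    "register_adapter",
    "get_adapter",
    "PHYSCHEM_FEATURES",
    "EISENBERG",
    "KYTE_DOOLITTLE",
    "BOMAN",
]


def _load_scale(name: str) -> dict[str, float]:
    """Load a vendored residue scale CSV (``# comment`` header allowed)."""
    path = resources.files("fitrank.data.scales").joinpath(f"{name}.csv")
    scale: dict[str, float] = {}
    with path.open("r") as handle:
        rows = [r for r in csv.reader(handle) if r and not r[0].startswith("#")]
    for residue, value in rows[1:]:  # rows[0] is the column header
        scale[residue] = float(value)
    if set(scale) != set(AA_ALPHABET):
        raise FitrankError(f"scale {name!r} does not cover the 20 canonical residues")
    return scale


EISENBERG = _load_scale("eisenberg")
KYTE_DOOLITTLE = _load_scale("kyte_doolittle")
BOMAN = _load_scale("boman")

_VALID = frozenset(AA_ALPHABET)
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: Residue groups used by composition descriptors.
HYDROPHOBIC_SET = frozenset("AFILMVW")
POSITIVE_SET = frozenset("HKR")
NEGATIVE_SET = frozenset("DE")
POLAR_SET = frozenset("NQSTY")
TINY_SET = frozenset("ACGST")


def _default_ids(sequences: Sequence[str]) -> list[str]:
    return [f"seq_{i:06d}" for i in range(len(sequences))]


def _check_canonical(sequences: Sequence[str]) -> None:
    for i, seq in enumerate(sequences):
        bad = set(seq) - _VALID
        if bad:
            raise FitrankError(
                f"sequence index {i} contains non-canonical characters {sorted(bad)}; "
                "run preprocessing.clean_sequences first"
            )


def encode_onehot(sequences: Sequence[str], ids: Sequence[str] | None = None) -> EncodingMatrix:
    """One-hot encode equal-length sequences into a 20·L indicator matrix.

    Channel order within each position is fixed alphabetical (ACDEFGHIKLMNPQRSTVWY).
    Raises :class:`RaggedLengthError` on mixed lengths.
    """
    sequences = list(sequences)
    if not sequences:
        raise FitrankError("cannot encode an empty sequence collection")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise RaggedLengthError(
            f"one-hot encoding requires equal-length sequences, got lengths {sorted(lengths)}; "
            "pad the sequences or encode a fixed-length subset"
        )
    _check_canonical(sequences)
    length = lengths.pop()
    values = np.zeros((len(sequences), 20 * length))
    for r, seq in enumerate(sequences):
        for pos, aa in enumerate(seq):
            values[r, pos * 20 + _AA_INDEX[aa]] = 1.0
    feature_names = [f"pos{p}_{aa}" for p in range(length) for aa in AA_ALPHABET]
    return EncodingMatrix(
        encoding_name="onehot",
        values=values,
        feature_names=feature_names,
        row_ids=list(ids) if ids is not None else _default_ids(sequences),
    )


def decode_onehot(matrix: EncodingMatrix) -> list[str]:
    """Invert :func:`encode_onehot` (exact for canonical encodings)."""
    n, width = matrix.shape
    if width % 20 != 0:
        raise FitrankError("matrix width is not a multiple of 20")
    length = width // 20
    blocks = matrix.values.reshape(n, length, 20)
    return ["".join(AA_ALPHABET[j] for j in row.argmax(axis=1)) for row in blocks]


# ---------------------------------------------------------------------------
# Physiochemical descriptors
# ---------------------------------------------------------------------------

#: The twenty descriptors, in fixed output order. The paper-adjacent trio is
#: h_eisenberg / boman_index / gravy; the complement (documented here because
#: no canonical twenty-descriptor list exists) is: basic size/charge globals,
#: Eisenberg-profile window statistics, and residue-class composition fractions.
PHYSCHEM_FEATURES: tuple[str, ...] = (
    "length",
    "molecular_weight",
    "charge_ph7",
    "charge_density",
    "isoelectric_point",
    "instability_index",
    "aromaticity",
    "aliphatic_index",
    "hydrophobic_ratio",
    "gravy",
    "boman_index",
    "h_eisenberg",
    "uh_eisenberg",
    "h_eisenberg_max_w11",
    "h_eisenberg_min_w11",
    "h_eisenberg_std",
    "fraction_positive",
    "fraction_negative",
    "fraction_polar",
    "fraction_tiny",
)

_DELTA = math.radians(100.0)  # helical twist used for the hydrophobic moment


def _eisenberg_profile(seq: str) -> np.ndarray:
    return np.array([EISENBERG[aa] for aa in seq])


def _hydrophobic_moment(profile: np.ndarray) -> float:
    angles = _DELTA * np.arange(len(profile))
    sin_sum = float(np.sum(profile * np.sin(angles)))
    cos_sum = float(np.sum(profile * np.cos(angles)))
    return math.hypot(sin_sum, cos_sum) / len(profile)


def _fraction(seq: str, residues: frozenset[str]) -> float:
    return sum(1 for aa in seq if aa in residues) / len(seq)


def _descriptor_vector(seq: str) -> np.ndarray:
    analysis = ProteinAnalysis(seq)
    length = len(seq)
    mw = analysis.molecular_weight()
    charge = analysis.charge_at_pH(7.0)
    profile = _eisenberg_profile(seq)
    window = min(11, length)
    # sliding window means over the Eisenberg profile
    kernel = np.ones(window) / window
    window_means = np.convolve(profile, kernel, mode="valid")
    counts = {aa: seq.count(aa) for aa in "AVIL"}
    aliphatic = 100.0 * (
        counts["A"] / length
        + 2.9 * counts["V"] / length
        + 3.9 * (counts["I"] + counts["L"]) / length
    )
    return np.array(
        [
            float(length),
            mw,
            charge,
            charge / mw,
            analysis.isoelectric_point(),
            analysis.instability_index(),
            analysis.aromaticity(),
            aliphatic,
            _fraction(seq, HYDROPHOBIC_SET),
            float(np.mean([KYTE_DOOLITTLE[aa] for aa in seq])),
            float(np.mean([BOMAN[aa] for aa in seq])),
            float(np.mean(profile)),
            _hydrophobic_moment(profile),
            float(np.max(window_means)),
            float(np.min(window_means)),
            float(np.std(profile)),
            _fraction(seq, POSITIVE_SET),
            _fraction(seq, NEGATIVE_SET),
            _fraction(seq, POLAR_SET),
            _fraction(seq, TINY_SET),
        ]
    )


def encode_physiochemical(
    sequences: Sequence[str], ids: Sequence[str] | None = None
) -> EncodingMatrix:
    """Encode each sequence as the twenty global descriptors in :data:`PHYSCHEM_FEATURES`."""
    sequences = list(sequences)
    if not sequences:
        raise FitrankError("cannot encode an empty sequence collection")
    _check_canonical(sequences)
    for i, seq in enumerate(sequences):
        if len(seq) < 2:
            raise FitrankError(
                f"sequence index {i} has length {len(seq)} < 2; "
                "window statistics are undefined"
            )
    values = np.stack([_descriptor_vector(seq) for seq in sequences])
    return EncodingMatrix(
        encoding_name="physchem",
        values=values,
        feature_names=list(PHYSCHEM_FEATURES),
        row_ids=list(ids) if ids is not None else _default_ids(sequences),
    )


# ---------------------------------------------------------------------------
# Embedding adapters
# ---------------------------------------------------------------------------


class EmbeddingAdapter(ABC):
    """Contract for fixed-vector sequence embedders.

    Implementations must be deterministic for a fixed configuration and emit
    exactly ``dimension`` features for every input sequence.
    """

    name: str
    dimension: int

    @abstractmethod
    def embed(self, sequences: Sequence[str]) -> np.ndarray:
        """Return an ``len(sequences) x dimension`` float matrix."""


class HashedKmerAdapter(EmbeddingAdapter):
    """Deterministic mock embedder: signed feature hashing of k-mer counts.

    Buckets and signs come from a keyed blake2b hash of each k-mer, so the
    mapping is independent of the input collection, Python's hash
    randomisation, and the platform. Composition information (1-mers) is
    preserved up to hash collisions, which keeps linear planted signals
    recoverable from the embedding.
    """

    def __init__(self, dimension: int = 64, kmer_sizes: tuple[int, ...] = (1,), seed: int = 0):
        if dimension < 1:
            raise FitrankError("adapter dimension must be positive")
        self.name = f"mock{dimension}"
        self.dimension = dimension
        self.kmer_sizes = kmer_sizes
        self.seed = seed
        self._key = seed.to_bytes(8, "little", signed=True)

    def _bucket(self, kmer: str) -> tuple[int, float]:
        digest = hashlib.blake2b(kmer.encode(), digest_size=8, key=self._key).digest()
        value = int.from_bytes(digest, "little")
        return value % self.dimension, 1.0 if (value >> 40) & 1 else -1.0

    def embed(self, sequences: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(sequences), self.dimension))
        for r, seq in enumerate(sequences):
            if not seq:
                raise FitrankError("cannot embed an empty sequence")
            for k in self.kmer_sizes:
                for i in range(len(seq) - k + 1):
                    bucket, sign = self._bucket(seq[i : i + k])
                    out[r, bucket] += sign
            out[r] /= len(seq)
        return out


_ADAPTERS: dict[str, EmbeddingAdapter] = {}


def register_adapter(adapter: EmbeddingAdapter) -> None:
    _ADAPTERS[adapter.name] = adapter


def get_adapter(name: str) -> EmbeddingAdapter:
    if name not in _ADAPTERS:
        raise FitrankError(
            f"no adapter registered under {name!r}; known: {sorted(_ADAPTERS)}"
        )
    return _ADAPTERS[name]


register_adapter(HashedKmerAdapter(dimension=64))


def encode_with_adapter(
    sequences: Sequence[str],
    adapter: EmbeddingAdapter,
    ids: Sequence[str] | None = None,
) -> EncodingMatrix:
    """Run an embedding adapter and validate its output against the contract."""
    sequences = list(sequences)
    if not sequences:
        raise FitrankError("cannot encode an empty sequence collection")
    try:
        values = adapter.embed(sequences)
    except Exception as exc:  # locate the offending sequence for context
        for i, seq in enumerate(sequences):
            try:
                adapter.embed([seq])
            except Exception:
                raise AdapterError(
                    f"adapter {adapter.name!r} failed on sequence index {i}: {exc}"
                ) from exc
        raise AdapterError(f"adapter {adapter.name!r} failed on the batch: {exc}") from exc
    values = np.asarray(values, dtype=float)
    if values.shape != (len(sequences), adapter.dimension):
        raise AdapterError(
            f"adapter {adapter.name!r} returned shape {values.shape}, "
            f"expected {(len(sequences), adapter.dimension)}"
        )
    return EncodingMatrix(
        encoding_name=adapter.name,
        values=values,
        feature_names=[f"{adapter.name}_{j}" for j in range(adapter.dimension)],
        row_ids=list(ids) if ids is not None else _default_ids(sequences),
    )


def encode_by_name(
    name: str, sequences: Sequence[str], ids: Sequence[str] | None = None
) -> EncodingMatrix:
    """Dispatch an encoding by registry name (``onehot``, ``physchem``, or an adapter name)."""
    if name == "onehot":
        return encode_onehot(sequences, ids)
    if name == "physchem":
        return encode_physiochemical(sequences, ids)
    adapter_name = name.removeprefix("adapter:")
    return encode_with_adapter(sequences, get_adapter(adapter_name), ids)
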