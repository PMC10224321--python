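import numpy as np
import pandas as pd
import pytest

from fitrank.exceptions import DegenerateMatrixError, FitrankError, MissingCellsError
from fitrank.mcda import (
    DecisionMatrix,
    WeightVector,
    build_decision_matrix,
    entropy_weights,
    subjective_weights,
    topsis_rank,
)
from fitrank.metrics import CRITERIA


# --- independent brute-force oracles (kept deliberately naive) -------------


def oracle_entropy_weights(x):
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    weights = []
    for j in range(m):
        column = x[:, j]
        r = column / column.sum()
        e = 0.0
        for value in r:
            if value > 0:
                e += value * np.log(value)
        weights.append(1.0 - (-(1.0 / np.log(n)) * e))
    total = sum(weights)
    return np.array([w / total for w in weights])


def oracle_topsis(x, weights, signs):
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    v = np.zeros_like(x)
    for j in range(m):
        norm = np.sqrt(sum(x[i, j] ** 2 for i in range(n)))
        for i in range(n):
            v[i, j] = weights[j] * x[i, j] / norm
    ideal = [max(v[:, j]) if signs[j] == 1 else min(v[:, j]) for j in range(m)]
    anti = [min(v[:, j]) if signs[j] == 1 else max(v[:, j]) for j in range(m)]
    closeness = []
    for i in range(n):
        d_pos = np.sqrt(sum((v[i, j] - ideal[j]) ** 2 for j in range(m)))
        d_neg = np.sqrt(sum((v[i, j] - anti[j]) ** 2 for j in range(m)))
        closeness.append(d_neg / (d_pos + d_neg))
    return np.array(closeness)


def _dm(x, signs=None, names=None):
    x = np.asarray(x, dtype=float)
    m = x.shape[1]
    return DecisionMatrix(
        x=x,
        alternative_ids=[f"alt{i}" for i in range(x.shape[0])],
        criterion_names=names or [f"c{j}" for j in range(m)],
        signs=signs or tuple([1] * m),
    )


class TestDecisionMatrix:
    def test_negative_entries_rejected(self):
        with pytest.raises(FitrankError, match="nonnegative"):
            _dm([[1.0, -0.1], [0.5, 0.2]])

    def test_zero_column_rejected(self):
        with pytest.raises(DegenerateMatrixError):
            _dm([[1.0, 0.0], [0.5, 0.0]])

    def test_default_signs(self):
        matrix = DecisionMatrix(
            x=np.ones((2, 6)) + np.arange(12).reshape(2, 6),
            alternative_ids=["a", "b"],
        )
        assert matrix.signs == (1, -1, 1, 1, 1, -1)
        assert matrix.criterion_names == list(CRITERIA)


class TestEntropyWeights:
    def test_identity_matrix_symmetric(self):
        weights = entropy_weights(_dm([[1.0, 0.0], [0.0, 1.0]]))
        assert weights.w == pytest.approx([0.5, 0.5])

    def test_uniform_column_gets_zero_weight(self):
        weights = entropy_weights(_dm([[0.5, 0.9], [0.5, 0.1]]))
        assert weights.w[0] == pytest.approx(0.0, abs=1e-12)

    def test_frozen_hand_computation(self):
        # frozen from an independent evaluation of the three-step formula
        weights = entropy_weights(_dm([[0.9, 0.1], [0.8, 0.2], [0.7, 0.3]]))
        assert weights.w == pytest.approx([0.05649661, 0.94350339], abs=1e-8)

    def test_all_uniform_degenerate(self):
        with pytest.raises(DegenerateMatrixError):
            entropy_weights(_dm([[0.5, 0.2], [0.5, 0.2]]))

    def test_property_sum_one_nonnegative(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 8))
            m = int(rng.integers(2, 7))
            x = rng.uniform(0.05, 1.0, size=(n, m))
            weights = entropy_weights(_dm(x))
            assert weights.w.sum() == pytest.approx(1.0)
            assert np.all(weights.w >= 0)

    def test_oracle_agreement(self, rng):
        for _ in range(200)[:200]:
            x = rng.uniform(0.01, 1.0, size=(4, 6))
            ours = entropy_weights(_dm(x)).w
            assert np.max(np.abs(ours - oracle_entropy_weights(x))) < 1e-10


class TestSubjectiveWeights:
    def test_default_emphasis(self):
        weights = subjective_weights()
        expected = {"F1": 0.15, "FPR": 0.20, "TPR": 0.15,
                    "precision": 0.20, "NPV": 0.15, "FDR": 0.15}
        assert weights.w == pytest.approx([expected[c] for c in CRITERIA])

    def test_uniform_input(self):
        weights = subjective_weights({c: 1.0 for c in CRITERIA})
        assert weights.w == pytest.approx([1 / 6] * 6)

    def test_scaled_uniform(self):
        weights = subjective_weights({c: 2.0 for c in CRITERIA})
        assert weights.w == pytest.approx([1 / 6] * 6)

    def test_negative_rejected(self):
        with pytest.raises(FitrankError):
            subjective_weights({"F1": -1.0})

    def test_unknown_criterion_rejected(self):
        with pytest.raises(FitrankError, match="unknown"):
            subjective_weights({"AUROC": 0.5})


class TestTopsis:
    def test_dominant_alternative_closeness_one(self):
        matrix = _dm([[0.9, 0.1], [0.5, 0.5], [0.2, 0.9]], signs=(1, -1))
        result = topsis_rank(matrix, WeightVector(np.array([0.5, 0.5]), "subjective"))
        assert result.closeness[0] == pytest.approx(1.0)
        assert result.ranks[0] == 1

    def test_dominated_alternative_closeness_zero(self):
        matrix = _dm([[0.9, 0.1], [0.5, 0.5], [0.2, 0.9]], signs=(1, -1))
        result = topsis_rank(matrix, WeightVector(np.array([0.5, 0.5]), "subjective"))
        assert result.closeness[2] == pytest.approx(0.0)
        assert result.ranks[2] == 3

    def test_frozen_toy_case(self):
        matrix = _dm([[0.7, 0.10], [0.8, 0.30], [0.6, 0.05]], signs=(1, -1))
        result = topsis_rank(matrix, WeightVector(np.array([0.5, 0.5]), "subjective"))
        assert result.closeness == pytest.approx(
            [0.78130395, 0.17343469, 0.82656531], abs=1e-8
        )

    def test_identical_alternatives_degenerate(self):
        with pytest.raises(DegenerateMatrixError):
            topsis_rank(
                _dm([[0.5, 0.5], [0.5, 0.5]]),
                WeightVector(np.array([0.5, 0.5]), "subjective"),
            )

    def test_oracle_agreement_200_random(self, rng):
        signs = (1, -1, 1, 1, 1, -1)
        weights = np.full(6, 1 / 6)
        for _ in range(200):
            x = rng.uniform(0.01, 1.0, size=(4, 6))
            matrix = _dm(x, signs=signs)
            ours = topsis_rank(matrix, WeightVector(weights, "subjective")).closeness
            assert np.max(np.abs(ours - oracle_topsis(x, weights, signs))) < 1e-10

    def test_scale_invariance(self, rng):
        x = rng.uniform(0.1, 1.0, size=(5, 6))
        signs = (1, -1, 1, 1, 1, -1)
        weights = WeightVector(np.full(6, 1 / 6), "subjective")
        base = topsis_rank(_dm(x, signs=signs), weights).closeness
        scaled_x = x.copy()
        scaled_x[:, 2] *= 37.5
        scaled = topsis_rank(_dm(scaled_x, signs=signs), weights).closeness
        assert scaled == pytest.approx(base)

    def test_dominance_never_inverted(self, rng):
        signs = (1, -1, 1)
        weights = WeightVector(np.full(3, 1 / 3), "subjective")
        for _ in range(100):
            x = rng.uniform(0.1, 1.0, size=(4, 3))
            # make row 0 weakly dominate row 1 on every oriented criterion
            x[0, 0] = x[1, 0] + 0.01
            x[0, 1] = max(x[1, 1] - 0.01, 0.01)
            x[0, 2] = x[1, 2] + 0.01
            result = topsis_rank(_dm(x, signs=signs), weights)
            assert result.closeness[0] >= result.closeness[1] - 1e-12

    def test_sum_normalization_variant(self, rng):
        x = rng.uniform(0.1, 1.0, size=(4, 6))
        weights = WeightVector(np.full(6, 1 / 6), "subjective")
        result = topsis_rank(_dm(x, signs=(1, -1, 1, 1, 1, -1)), weights,
                             normalization="sum")
        assert np.all((result.closeness >= 0) & (result.closeness <= 1))

    def test_ranks_are_bijection(self, rng):
        x = rng.uniform(0.1, 1.0, size=(6, 6))
        weights = WeightVector(np.full(6, 1 / 6), "subjective")
        result = topsis_rank(_dm(x, signs=(1, -1, 1, 1, 1, -1)), weights)
        assert sorted(result.ranks) == [1, 2, 3, 4, 5, 6]


def _replicate_frame():
    rows = []
    for alt, base in (("alt_a", 0.8), ("alt_b", 0.6)):
        for seed in (0, 1, 2):
            rows.append(
                {
                    "alternative": alt, "seed": seed,
                    "F1": base + 0.01 * seed, "FPR": 0.1, "TPR": base,
                    "precision": base, "NPV": 0.9, "FDR": 1 - base,
                }
            )
    return pd.DataFrame(rows)


class TestBuildDecisionMatrix:
    def test_seed_means(self):
        matrix = build_decision_matrix(_replicate_frame())
        assert matrix.alternative_ids == ["alt_a", "alt_b"]
        f1_col = matrix.criterion_names.index("F1")
        assert matrix.x[0, f1_col] == pytest.approx(0.81)

    def test_criterion_order_fixed(self):
        frame = _replicate_frame()[
            ["seed", "FDR", "NPV", "precision", "TPR", "FPR", "F1", "alternative"]
        ]
        matrix = build_decision_matrix(frame)
        assert matrix.criterion_names == list(CRITERIA)

    def test_single_seed_rejected(self):
        frame = _replicate_frame()
        with pytest.raises(MissingCellsError):
            build_decision_matrix(frame[frame["seed"] == 0])

    def test_missing_cell_listed(self):
        frame = _replicate_frame()
        frame = frame.drop(frame[(frame["alternative"] == "alt_b")
                                 & (frame["seed"] == 2)].index)
        with pytest.raises(MissingCellsError, match="alt_b"):
            build_decision_matrix(frame)
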