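import numpy as np
import pytest

from fitrank.datatypes import EncodingMatrix
from fitrank.exceptions import FitrankError, SingleClassError
from fitrank.modeling import (
    Alternative,
    ClassifierSpec,
    RegressorSpec,
    evaluate_classifier,
    fit_regressor,
    run_replicates,
    train_classifier,
)


def _separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    neg = rng.normal(loc=-3.0, scale=0.3, size=(n, 2))
    pos = rng.normal(loc=3.0, scale=0.3, size=(n, 2))
    features = np.vstack([neg, pos])
    labels = np.array([0] * n + [1] * n)
    return features, labels


class TestClassifier:
    def test_separable_training_accuracy(self):
        features, labels = _separable()
        handle = train_classifier(features, labels)
        assert (handle.predict(features) == labels).all()

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            train_classifier(np.zeros((5, 2)), np.ones(5, dtype=int))

    def test_constant_feature_column_ok(self):
        features, labels = _separable()
        features = np.hstack([features, np.ones((len(features), 1))])
        handle = train_classifier(features, labels, ClassifierSpec(standardize=False))
        assert (handle.predict(features) == labels).mean() > 0.95

    def test_probabilities_in_unit_interval(self):
        features, labels = _separable()
        handle = train_classifier(features, labels)
        probs = handle.predict_proba_positive(features)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_nonconvergence_warns_with_iteration_count(self):
        features, labels = _separable(n=100, seed=2)
        with pytest.warns(UserWarning, match="converge"):
            train_classifier(
                features, labels, ClassifierSpec(max_iterations=1, standardize=False)
            )

    def test_evaluate_empty_rejected(self):
        features, labels = _separable()
        handle = train_classifier(features, labels)
        with pytest.raises(FitrankError):
            evaluate_classifier(handle, np.empty((0, 2)), np.array([]))

    def test_evaluate_report(self):
        features, labels = _separable()
        handle = train_classifier(features, labels)
        report = evaluate_classifier(handle, features, labels)
        assert report.f1 == 1.0 and report.fpr == 0.0


class TestRegressor:
    def test_easy_linear_target(self):
        rng = np.random.default_rng(1)
        features = rng.uniform(size=(300, 3))
        targets = 2.0 * features[:, 0] - features[:, 1]
        spec = RegressorSpec(
            n_estimators_range=(50, 100), max_depth_range=(4, 12), search_budget=5
        )
        handle, params, _ = fit_regressor(features[:200], targets[:200], spec, seed=0)
        from fitrank.metrics import regression_metrics

        report = regression_metrics(targets[200:], handle.predict(features[200:]))
        assert report.r2 >= 0.9

    def test_params_within_ranges(self):
        rng = np.random.default_rng(2)
        features = rng.uniform(size=(60, 2))
        targets = features.sum(axis=1)
        spec = RegressorSpec(
            n_estimators_range=(10, 20), max_depth_range=(2, 4), search_budget=4
        )
        _, params, _ = fit_regressor(features, targets, spec, seed=1)
        assert 10 <= params["n_estimators"] <= 20
        assert 2 <= params["max_depth"] <= 4

    def test_too_few_rows(self):
        with pytest.raises(FitrankError, match="20"):
            fit_regressor(np.zeros((10, 2)), np.zeros(10))

    def test_zero_budget(self):
        with pytest.raises(FitrankError, match="budget"):
            fit_regressor(
                np.zeros((30, 2)), np.arange(30.0), RegressorSpec(search_budget=0)
            )


def _toy_encodings(n=120, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array([0] * (n - n // 6) + [1] * (n // 6))
    signal = labels * 2.0 + rng.normal(scale=0.8, size=n)
    enc_a = EncodingMatrix(
        "enc_a",
        np.column_stack([signal, rng.normal(size=n)]),
        ["s", "noise"],
        [f"r{i}" for i in range(n)],
    )
    enc_b = EncodingMatrix(
        "enc_b",
        np.column_stack([signal + rng.normal(scale=0.3, size=n), rng.normal(size=n)]),
        ["s2", "noise2"],
        [f"r{i}" for i in range(n)],
    )
    return {"enc_a": enc_a, "enc_b": enc_b}, labels


class TestRunReplicates:
    def test_row_count(self):
        encodings, labels = _toy_encodings()
        alternatives = [
            Alternative(id="a_SM", encodings=("enc_a",), sampler="smote"),
            Alternative(id="b_SM", encodings=("enc_b",), sampler="smote"),
            Alternative(id="ab_vote", encodings=("enc_a", "enc_b"), sampler="smote",
                        combine="vote"),
        ]
        table = run_replicates(encodings, labels, alternatives, seeds=range(20))
        assert len(table.frame) == 60
        assert table.ok

    def test_duplicate_alternative_identical_rows(self):
        encodings, labels = _toy_encodings()
        alternatives = [
            Alternative(id="first", encodings=("enc_a",), sampler="over"),
            Alternative(id="second", encodings=("enc_a",), sampler="over"),
        ]
        table = run_replicates(encodings, labels, alternatives, seeds=[0, 1, 2])
        a = table.frame[table.frame["alternative"] == "first"].drop(columns="alternative")
        b = table.frame[table.frame["alternative"] == "second"].drop(columns="alternative")
        assert a.reset_index(drop=True).equals(b.reset_index(drop=True))

    def test_single_seed_rejected(self):
        encodings, labels = _toy_encodings()
        with pytest.raises(FitrankError, match="2 seeds"):
            run_replicates(
                encodings, labels,
                [Alternative(id="a", encodings=("enc_a",))], seeds=[1],
            )

    def test_unknown_encoding_rejected(self):
        encodings, labels = _toy_encodings()
        with pytest.raises(FitrankError, match="unknown encoding"):
            run_replicates(
                encodings, labels,
                [Alternative(id="x", encodings=("missing",))], seeds=[0, 1],
            )

    def test_row_count_mismatch_guard(self):
        encodings, labels = _toy_encodings()
        bad = EncodingMatrix("bad", np.zeros((3, 1)), ["z"], ["r0", "r1", "r2"])
        with pytest.raises(FitrankError):
            run_replicates(
                {**encodings, "bad": bad}, labels,
                [Alternative(id="bad", encodings=("bad",))], seeds=[0, 1],
            )

    def test_failed_cell_recorded_run_continues(self, monkeypatch):
        import fitrank.modeling as modeling

        encodings, labels = _toy_encodings()
        real_train = modeling.train_classifier
        calls = {"n": 0}

        def flaky(features, train_labels, spec, seed):
            calls["n"] += 1
            if seed == 1:
                raise RuntimeError("injected failure")
            return real_train(features, train_labels, spec, seed)

        monkeypatch.setattr(modeling, "train_classifier", flaky)
        table = run_replicates(
            encodings, labels,
            [Alternative(id="a", encodings=("enc_a",), sampler="over")],
            seeds=[0, 1, 2],
        )
        assert not table.ok
        assert [(alt, seed) for alt, seed, _ in table.failures] == [("a", 1)]
        assert sorted(table.frame["seed"]) == [0, 2]

    def test_concat_alternative(self):
        encodings, labels = _toy_encodings()
        table = run_replicates(
            encodings, labels,
            [Alternative(id="cat", encodings=("enc_a", "enc_b"), combine="concat",
                         sampler="over")],
            seeds=[0, 1, 2],
        )
        assert len(table.frame) == 3

    def test_paired_design_mean_f1_above_baseline(self, small_labeled):
        # planted-signal parameter recovery: physchem LR beats the no-skill baseline
        from fitrank.encoders import encode_by_name

        encodings = {
            "physchem": encode_by_name("physchem", small_labeled.sequences,
                                       small_labeled.ids)
        }
        table = run_replicates(
            encodings, small_labeled.labels,
            [Alternative(id="phys_SM", encodings=("physchem",), sampler="smote")],
            seeds=range(5),
        )
        prevalence = small_labeled.n_positive / len(small_labeled)
        assert table.frame["F1"].mean() > prevalence


class TestAlternativeGuards:
    def test_single_requires_one_encoding(self):
        with pytest.raises(FitrankError):
            Alternative(id="x", encodings=("a", "b"), combine="single")

    def test_vote_requires_two(self):
        with pytest.raises(FitrankError):
            Alternative(id="x", encodings=("a",), combine="vote")

    def test_unknown_combine(self):
        with pytest.raises(FitrankError):
            Alternative(id="x", encodings=("a",), combine="stack")
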