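"""LSTM head training, prediction contracts, folds, and extractor comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestseg.crossval import compare_extractors, make_grouped_folds
from gestseg.head import LSTMGestureClassifier
from gestseg.synthetic import CohortSpec, GestureGrammar, generate_cohort


def make_sequences(rng, n=80, T=25, dim=12, n_classes=6, separation=4.0):
    """Sequences with piecewise-constant labels and Gaussian class features."""
    means = rng.standard_normal((n_classes, dim))
    means *= separation / np.linalg.norm(means, axis=1, keepdims=True)
    X = np.empty((n, T, dim))
    y = np.empty((n, T), dtype=np.int64)
    for i in range(n):
        lab = rng.integers(0, n_classes)
        switch = rng.integers(5, T)
        lab2 = rng.integers(0, n_classes)
        y[i, :switch] = lab
        y[i, switch:] = lab2
        X[i] = means[y[i]] + rng.standard_normal((T, dim))
    return X, y


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    return make_sequences(rng, n=120, separation=5.0)


class TestTraining:
    def test_separable_data_high_accuracy(self, separable):
        X, y = separable
        head = LSTMGestureClassifier(hidden_units=32, epochs=10, batch_size=16,
                                     learning_rate=1e-2, random_state=0)
        head.fit(X, y)
        assert max(head.history_["val_accuracy"]) >= 0.95

    def test_no_signal_gives_chance_accuracy(self):
        rng = np.random.default_rng(1)
        X, y = make_sequences(rng, n=80, separation=0.0)
        head = LSTMGestureClassifier(hidden_units=16, epochs=5, random_state=0)
        head.fit(X, y)
        # best achievable is the majority-class rate of the validation labels
        acc = head.history_["val_accuracy"][-1]
        assert acc < 0.45

    def test_same_seed_identical_loss(self, separable):
        X, y = separable
        losses = []
        for _ in range(2):
            head = LSTMGestureClassifier(hidden_units=16, epochs=3, random_state=7)
            head.fit(X, y)
            losses.append(head.history_["train_loss"][-1])
        assert losses[0] == losses[1]

    def test_missing_class_warns(self):
        rng = np.random.default_rng(2)
        X, y = make_sequences(rng, n=30)
        y[y == 5] = 4
        head = LSTMGestureClassifier(hidden_units=8, epochs=1, random_state=0)
        with pytest.warns(UserWarning, match="absent"):
            head.fit(X, y)

    def test_bad_shapes_rejected(self):
        head = LSTMGestureClassifier()
        with pytest.raises(ValueError):
            head.fit(np.zeros((4, 25)), np.zeros((4, 25)))

    def test_sklearn_param_interface(self):
        head = LSTMGestureClassifier(hidden_units=64)
        assert head.get_params()["hidden_units"] == 64
        head.set_params(epochs=3)
        assert head.epochs == 3

    def test_save_load_roundtrip(self, separable, tmp_path):
        X, y = separable
        head = LSTMGestureClassifier(hidden_units=16, epochs=2, random_state=0)
        head.fit(X, y)
        head.save(tmp_path / "head.npz")
        back = LSTMGestureClassifier.load(tmp_path / "head.npz")
        np.testing.assert_array_equal(head.predict(X[:4]), back.predict(X[:4]))


class TestPrediction:
    def test_rows_on_simplex(self, separable):
        X, y = separable
        head = LSTMGestureClassifier(hidden_units=16, epochs=2, random_state=0)
        head.fit(X, y)
        P = head.predict_proba(X[:10])
        assert P.shape == (10, 25, 6)
        np.testing.assert_allclose(P.sum(axis=-1), 1.0, atol=1e-6)
        assert (P > 0).all() and (P < 1).all()

    def test_duplicate_inputs_identical_outputs(self, separable):
        X, y = separable
        head = LSTMGestureClassifier(hidden_units=16, epochs=2, random_state=0)
        head.fit(X, y)
        P = head.predict_proba(np.stack([X[0], X[0]]))
        np.testing.assert_array_equal(P[0], P[1])

    def test_dim_mismatch_rejected(self, separable):
        X, y = separable
        head = LSTMGestureClassifier(hidden_units=16, epochs=1, random_state=0)
        head.fit(X, y)
        with pytest.raises(ValueError, match="dim"):
            head.predict_proba(np.zeros((1, 25, 99)))

    def test_argmax_matches_truth_on_separable(self, separable):
        X, y = separable
        head = LSTMGestureClassifier(hidden_units=32, epochs=10, batch_size=16,
                                     learning_rate=1e-2, random_state=0)
        head.fit(X, y)
        assert head.score(X, y) >= 0.95


@pytest.fixture(scope="module")
def tracks():
    return generate_cohort(CohortSpec(seed=0),
                           GestureGrammar(video_duration_s=30.0))


class TestFoldPlan:
    def test_seven_folds_one_experienced_each(self, tracks):
        plan = make_grouped_folds(tracks, k=7, seed=0)
        assert plan.k == 7
        for f in plan.folds:
            exp = [s for s in f.test_ids if s.startswith("E")]
            assert len(exp) == 1

    def test_test_sets_partition_surgeons(self, tracks):
        plan = make_grouped_folds(tracks, k=7, seed=0)
        all_test = [s for f in plan.folds for s in f.test_ids]
        assert sorted(all_test) == sorted({t.surgeon_id for t in tracks})

    def test_no_surgeon_spans_train_and_test(self, tracks):
        plan = make_grouped_folds(tracks, k=7, seed=0)
        for f in plan.folds:
            assert not set(f.train_ids) & set(f.test_ids)
            assert not set(f.val_ids) & set(f.test_ids)

    def test_deterministic(self, tracks):
        a = make_grouped_folds(tracks, k=7, seed=3)
        b = make_grouped_folds(tracks, k=7, seed=3)
        assert a == b

    def test_too_few_experienced_rejected(self):
        tracks = generate_cohort(CohortSpec(n_novice=3, n_experienced=2,
                                            repetitions=1, seed=0),
                                 GestureGrammar(video_duration_s=20.0))
        with pytest.raises(ValueError, match="experienced"):
            make_grouped_folds(tracks, k=7)

    @settings(deadline=None, max_examples=10)
    @given(seed=st.integers(0, 10_000))
    def test_invariants_hold_for_all_seeds(self, tracks, seed):
        plan = make_grouped_folds(tracks, k=7, seed=seed)
        sizes = [len(f.test_ids) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1
        covered = sorted(s for f in plan.folds for s in f.test_ids)
        assert covered == sorted({t.surgeon_id for t in tracks})


class TestCompareExtractors:
    def _dataset(self, separation):
        rng = np.random.default_rng(0)
        X, y = make_sequences(rng, n=60, dim=8, separation=separation)
        groups = np.repeat([f"s{i}" for i in range(6)], 10)
        return X, y, groups

    def test_signal_beats_constant_features(self):
        Xs, ys, gs = self._dataset(separation=5.0)

        class Sig:
            name = "signal"

        class Flat:
            name = "flat"

        def provider(ext):
            if ext.name == "signal":
                return Xs, ys, gs
            return np.ones_like(Xs), ys, gs

        table = compare_extractors([Sig(), Flat()], provider, n_splits=2,
                                   seed=0, head_params={"hidden_units": 16,
                                                        "epochs": 8,
                                                        "batch_size": 16,
                                                        "learning_rate": 1e-2})
        assert table.iloc[0]["extractor"] == "signal"
        assert (table.set_index("extractor").loc["signal", "mean_accuracy"]
                > table.set_index("extractor").loc["flat", "mean_accuracy"] + 0.2)

    def test_identical_extractors_indistinguishable(self):
        Xs, ys, gs = self._dataset(separation=3.0)

        class A:
            name = "a"

        class B:
            name = "b"

        table = compare_extractors([A(), B()], lambda e: (Xs, ys, gs),
                                   n_splits=3, seed=1,
                                   head_params={"hidden_units": 8, "epochs": 3})
        t = table.set_index("extractor")
        gap = abs(t.loc["a", "mean_accuracy"] - t.loc["b", "mean_accuracy"])
        spread = 2 * (t.loc["a", "sd_accuracy"] + t.loc["b", "sd_accuracy"]) + 0.05
        assert gap <= spread

    def test_requires_two_extractors(self):
        with pytest.raises(ValueError):
            compare_extractors([object()], lambda e: None)
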