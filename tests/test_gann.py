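"""Split arithmetic, network training, GA invariants and blind evaluation."""

import numpy as np
import pytest

from blastograde.errors import (ConfigurationError, SchemaError,
                                StratificationError)
from blastograde.gann import (ANNGenome, GAConfig, SplitSpec, TrainedANN,
                              evaluate_blind, exact_accuracy, ga_evolve,
                              largest_remainder_sizes, predict_grade,
                              predict_proba, split_dataset, train_ann)


def _blobs(n_per_class=100, sep=3.0, dim=24, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(loc=c * sep, scale=1.0, size=(n_per_class, dim))
                   for c in range(3)])
    y = np.repeat([1, 2, 3], n_per_class)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


class TestSplit:
    @pytest.mark.parametrize("n,expected", [
        (126, (88, 19, 19)),   # largest-remainder on 0.70/0.15/0.15
        (100, (70, 15, 15)),
        (20, (14, 3, 3)),
    ])
    def test_largest_remainder_sizes(self, n, expected):
        assert tuple(largest_remainder_sizes(
            n, (0.70, 0.15, 0.15))) == expected

    @pytest.mark.parametrize("stratified", [True, False])
    def test_partition_contract(self, stratified):
        labels = np.tile([1, 2, 3], 42)
        tr, va, te = split_dataset(126, SplitSpec(stratified=stratified,
                                                  seed=3), labels)
        allidx = np.concatenate([tr, va, te])
        assert len(allidx) == 126
        assert len(np.unique(allidx)) == 126
        assert (len(tr), len(va), len(te)) == (88, 19, 19)

    def test_stratified_covers_every_class(self):
        rng = np.random.default_rng(0)
        labels = rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1], size=126)
        tr, va, te = split_dataset(126, SplitSpec(seed=1), labels)
        for idx in (tr, va, te):
            assert set(labels[idx]) == {1, 2, 3}

    def test_deterministic_for_fixed_seed(self):
        labels = np.tile([1, 2, 3], 42)
        a = split_dataset(126, SplitSpec(seed=9), labels)
        b = split_dataset(126, SplitSpec(seed=9), labels)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_tiny_class_raises_under_stratification(self):
        labels = np.array([1] * 124 + [2, 3])
        with pytest.raises(StratificationError):
            split_dataset(126, SplitSpec(seed=0), labels)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            SplitSpec(train_fraction=0.8, valid_fraction=0.3,
                      test_fraction=0.15)


class TestTrainANN:
    def test_learns_separable_data(self):
        X, y = _blobs(100, sep=3.0)
        model = train_ann(ANNGenome(hidden_sizes=(16,), epochs=60), X, y)
        assert exact_accuracy(model, X, y) >= 0.95

    def test_agrees_with_sklearn_on_separable_data(self):
        """Independent cross-check: an off-the-shelf MLP reaches the same
        regime on the same data."""
        from sklearn.neural_network import MLPClassifier
        X, y = _blobs(80, sep=3.0, seed=4)
        ours = train_ann(ANNGenome(hidden_sizes=(16,), epochs=60), X, y)
        ref = MLPClassifier(hidden_layer_sizes=(16,), max_iter=500,
                            random_state=0).fit(X, y)
        assert exact_accuracy(ours, X, y) >= 0.95
        assert ref.score(X, y) >= 0.95

    def test_zero_epochs_returns_initialization(self):
        X, y = _blobs(20)
        g = ANNGenome(epochs=0, weight_seed=5)
        model = train_ann(g, X, y)
        assert model.train_loss_curve == []
        from blastograde.gann import _init_layers
        W0, b0 = _init_layers(g, X.shape[1])
        for w, w0 in zip(model.weights, W0):
            assert np.array_equal(w, w0)

    def test_seeded_determinism(self):
        X, y = _blobs(50)
        g = ANNGenome(hidden_sizes=(8,), epochs=20, weight_seed=3)
        a, b = train_ann(g, X, y), train_ann(g, X, y)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_bad_labels_rejected(self):
        X, _ = _blobs(20)
        with pytest.raises(SchemaError):
            train_ann(ANNGenome(epochs=1), X, np.zeros(len(X), dtype=int))


class TestPredict:
    def _model(self):
        X, y = _blobs(60)
        return train_ann(ANNGenome(hidden_sizes=(8,), epochs=40), X, y), X, y

    def test_probabilities_sum_to_one(self):
        model, X, _ = self._model()
        probs = predict_proba(model, X[:10])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_memorizes_training_point(self):
        model, X, y = self._model()
        grade, _ = predict_grade(model, X[0])
        assert grade == y[0]

    def test_tie_breaks_toward_lower_grade(self):
        g = ANNGenome(hidden_sizes=(2,), epochs=0, weight_seed=0)
        model = train_ann(g, np.zeros((12, 4)), np.tile([1, 2, 3], 4))
        # zero weights: all logits equal -> exact three-way tie
        model.weights = [np.zeros_like(w) for w in model.weights]
        model.biases = [np.zeros_like(b) for b in model.biases]
        grade, probs = predict_grade(model, np.ones(4))
        assert np.allclose(probs, 1 / 3)
        assert grade == 1

    def test_wrong_dimension_raises(self):
        model, _, _ = self._model()
        with pytest.raises(SchemaError):
            predict_grade(model, np.zeros(7))


class TestGA:
    def test_best_fitness_non_decreasing(self):
        X, y = _blobs(40, sep=1.0, seed=2)
        _, _, pop = ga_evolve(GAConfig(n_islands=1, island_size=4,
                                       generations=4, seed=1),
                              X[:90], y[:90], X[90:], y[90:])
        hist = pop.best_history
        assert all(a <= b for a, b in zip(hist, hist[1:]))

    def test_seeded_rerun_identical(self):
        X, y = _blobs(40, sep=1.5, seed=3)
        cfg = GAConfig(n_islands=1, island_size=4, generations=2, seed=7)
        g1, _, _ = ga_evolve(cfg, X[:90], y[:90], X[90:], y[90:])
        g2, _, _ = ga_evolve(cfg, X[:90], y[:90], X[90:], y[90:])
        assert g1.as_tuple() == g2.as_tuple()

    def test_evolved_beats_default_genome(self):
        """After 20 generations the evolved genome's validation accuracy is
        at least that of an untuned default network."""
        rng = np.random.default_rng(11)
        X, y = _blobs(60, sep=0.8, seed=11)
        noisy = X + rng.normal(scale=1.0, size=X.shape)
        tr, va = slice(0, 120), slice(120, 180)
        default = train_ann(ANNGenome(), noisy[tr], y[tr])
        base = exact_accuracy(default, noisy[va], y[va])
        _, best, pop = ga_evolve(GAConfig(n_islands=2, island_size=6,
                                          generations=20, seed=11),
                                 noisy[tr], y[tr], noisy[va], y[va])
        assert pop.best_history[-1] >= base

    def test_empty_validation_raises(self):
        X, y = _blobs(20)
        with pytest.raises(ConfigurationError):
            ga_evolve(GAConfig(n_islands=1, island_size=4, generations=1),
                      X, y, X[:0], y[:0])


class TestEvaluateBlind:
    def _const_model(self, const_grade):
        class Fake:
            pass
        X, y = _blobs(20)
        model = train_ann(ANNGenome(hidden_sizes=(2,), epochs=0), X, y)
        model.weights = [np.zeros_like(w) for w in model.weights]
        model.biases = [np.zeros_like(b) for b in model.biases]
        model.biases[-1][const_grade - 1] = 10.0
        return model

    def test_perfect_predictor(self):
        X, y = _blobs(60, sep=4.0)
        model = train_ann(ANNGenome(hidden_sizes=(16,), epochs=80), X, y)
        rep = evaluate_blind(model, X, y)
        assert rep.exact_accuracy == 1.0
        assert rep.critical_errors == 0

    def test_constant_grade2_has_no_critical_errors(self):
        model = self._const_model(2)
        X, y = _blobs(30, seed=5)
        rep = evaluate_blind(model, X, y)
        assert rep.critical_errors == 0
        assert rep.exact_accuracy == pytest.approx(np.mean(y == 2))

    def test_hand_counted_confusion(self):
        model = self._const_model(1)
        X, y = _blobs(30, seed=6)
        y6, X6 = y[:6], X[:6]
        rep = evaluate_blind(model, X6, y6)
        # constant grade-1 predictor: column 0 carries everything
        expected = np.zeros((3, 3), dtype=int)
        for t in y6:
            expected[t - 1, 0] += 1
        assert np.array_equal(rep.confusion, expected)
        assert rep.critical_errors == expected[2, 0]
        assert rep.n_test == 6
        assert rep.confusion.sum() == 6


def test_no_leakage_scaler_fit_on_train_only():
    """The stored z-score parameters must equal a train-only refit."""
    X, y = _blobs(60, seed=8)
    tr = np.arange(0, 120)
    model = train_ann(ANNGenome(epochs=5), X[tr], y[tr])
    assert np.array_equal(model.scaler_mean, X[tr].mean(axis=0))
    sd = X[tr].std(axis=0)
    assert np.array_equal(model.scaler_sd, np.where(sd > 0, sd, 1.0))
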