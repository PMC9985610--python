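"""Successor-prediction network: training, assembly, metrics."""

import numpy as np
import pytest

from cogmap import (
    NetworkConfig,
    SemanticSpace,
    TrainedModel,
    accuracy,
    assemble_sr_matrix,
    bayes_ceiling,
    compute_sr_matrix,
    compute_transition_matrix,
    generate_samples,
    rmse,
    train,
)


def toy_space(positions, names=None):
    positions = np.asarray(positions, dtype=float).reshape(-1, 1)
    names = names or [f"s{i}" for i in range(len(positions))]
    return SemanticSpace(names, positions, ["x"])


@pytest.fixture(scope="module")
def two_state_run():
    """A 2-state space trained to convergence (small but full protocol)."""
    space = toy_space([0.5, 1.5])
    sr = compute_sr_matrix(compute_transition_matrix(space), 0.7, 10)
    samples = generate_samples(space, sr, n_samples=4000, seed=0, perturbation=0.15)
    # a single-feature space needs a few hidden units to avoid dead ReLUs
    config = NetworkConfig(n_input=1, n_hidden=4, n_output=2, epochs=300, seed=1)
    return space, sr, train(space, samples, config)


class TestRmse:
    def test_identical_matrices(self):
        a = np.random.default_rng(0).random((4, 4))
        assert rmse(a, a) == 0.0

    def test_all_entries_differ_by_one(self):
        assert rmse(np.array([[0.0, 1.0], [1.0, 0.0]]), np.eye(2)) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rmse(np.ones((2, 2)), np.ones((3, 3)))


class TestAccuracy:
    def test_constant_predictor_scores_label_frequency(self):
        # bias forces argmax to class 2 regardless of input
        cfg = NetworkConfig(n_input=2, n_hidden=2, n_output=3)
        b2 = np.array([0.0, 0.0, 5.0])
        model = TrainedModel(cfg, np.zeros((2, 2)), np.zeros(2), np.zeros((2, 3)), b2)
        X = np.random.default_rng(0).random((10, 2))
        y = np.array([2, 2, 2, 0, 1, 2, 2, 1, 0, 2])
        assert accuracy(model, X, y) == pytest.approx((y == 2).mean())

    def test_uniform_model_near_chance_on_balanced_labels(self):
        cfg = NetworkConfig(n_input=2, n_hidden=2, n_output=32)
        model = TrainedModel(cfg, np.zeros((2, 2)), np.zeros(2), np.zeros((2, 32)), np.zeros(32))
        # all-zero weights -> uniform softmax; argmax ties -> lowest index 0
        X = np.random.default_rng(1).random((320, 2))
        y = np.tile(np.arange(32), 10)
        assert accuracy(model, X, y) == pytest.approx(1 / 32)

    def test_empty_samples_rejected(self, two_state_run):
        _, _, model = two_state_run
        with pytest.raises(ValueError):
            accuracy(model, np.empty((0, 1)), np.empty(0, dtype=int))


class TestTraining:
    def test_zero_epochs_untrained_baseline(self):
        space = toy_space([0.0, 1.0, 2.0])
        sr = compute_sr_matrix(compute_transition_matrix(space), 0.5, 10)
        samples = generate_samples(space, sr, n_samples=100, seed=0)
        model = train(space, samples, NetworkConfig.for_space(space, epochs=0, seed=0))
        assert model.history["loss"] == []
        p = model.predict_proba(space.features)
        np.testing.assert_allclose(p, 1 / 3, atol=0.25)

    def test_softmax_rows_sum_to_one(self, two_state_run):
        _, _, model = two_state_run
        X = np.random.default_rng(2).random((50, 1)) * 3
        P = model.predict_proba(X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(P >= 0)

    def test_history_lengths_match_epochs(self, two_state_run):
        _, _, model = two_state_run
        assert len(model.history["loss"]) == 300
        assert len(model.history["val_accuracy"]) == 300

    def test_loss_decreases_with_training(self, two_state_run):
        _, _, model = two_state_run
        loss = model.history["loss"]
        assert loss[-1] < loss[0]

    def test_two_state_model_recovers_normalized_sr(self, two_state_run):
        """Converged 2-state network reproduces the closed-form SR rows."""
        space, sr, model = two_state_run
        learned = assemble_sr_matrix(model, space)
        np.testing.assert_allclose(learned, sr.normalized, atol=0.05)
        assert rmse(learned, sr.normalized) < 0.05

    def test_validation_accuracy_approaches_bayes_ceiling(self):
        """Near-deterministic successor rows: accuracy ~ mean max row prob."""
        space = toy_space([1.0, 10.0, 11.0])
        sr = compute_sr_matrix(compute_transition_matrix(space), 0.3, 10)
        samples = generate_samples(space, sr, n_samples=6000, seed=2, perturbation=0.0)
        config = NetworkConfig(n_input=1, n_hidden=4, n_output=3, epochs=200, seed=3)
        model = train(space, samples, config)
        ceiling = bayes_ceiling(sr)
        val_acc = np.mean(model.history["val_accuracy"][-20:])
        n_val = len(samples.val_indices)
        sigma = np.sqrt(ceiling * (1 - ceiling) / n_val)
        assert val_acc <= ceiling + 3 * sigma
        assert val_acc >= ceiling - 0.08

    def test_determinism_under_fixed_seed(self):
        space = toy_space([0.0, 1.0, 2.0])
        sr = compute_sr_matrix(compute_transition_matrix(space), 0.5, 10)
        samples = generate_samples(space, sr, n_samples=200, seed=5)
        cfg = NetworkConfig.for_space(space, epochs=5, seed=7)
        m1 = train(space, samples, cfg)
        m2 = train(space, samples, cfg)
        np.testing.assert_array_equal(m1.W1, m2.W1)
        np.testing.assert_array_equal(m1.W2, m2.W2)

    def test_empty_sample_set_rejected(self, animals_train, make_animals_sr):
        samples = generate_samples(animals_train, make_animals_sr(0.7), n_samples=10, seed=0)
        empty = type(samples)(
            inputs=samples.inputs[:0],
            labels=samples.labels[:0],
            train_indices=samples.train_indices[:0],
            val_indices=samples.val_indices[:0],
            seed=0,
        )
        with pytest.raises(ValueError):
            train(animals_train, empty)


class TestAssembleSR:
    def test_rows_are_probability_vectors(self, two_state_run):
        space, _, model = two_state_run
        learned = assemble_sr_matrix(model, space)
        np.testing.assert_allclose(learned.sum(axis=1), 1.0, atol=1e-6)

    def test_state_count_mismatch_rejected(self, two_state_run, animals_train):
        _, _, model = two_state_run
        with pytest.raises(ValueError):
            assemble_sr_matrix(model, animals_train)


def test_model_json_roundtrip(two_state_run):
    space, _, model = two_state_run
    again = TrainedModel.from_json(model.to_json())
    np.testing.assert_array_equal(again.W1, model.W1)
    np.testing.assert_array_equal(again.b2, model.b2)
    assert again.config == model.config
    X = np.array([[0.3], [0.9]])
    np.testing.assert_allclose(again.predict_proba(X), model.predict_proba(X))
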