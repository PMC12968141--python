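"""Training loop: determinism, history integrity, convergence, checkpoints."""

import numpy as np
import pytest

from odepinn import (
    NetworkSpec,
    ObservationSet,
    PinnModel,
    TrainHistory,
    TrainableODEParameters,
    TrainingConfig,
    checkpoint,
    has_converged,
    logistic_analytic,
    logistic_system,
    restore,
    sample_collocation,
    train,
)

LOGISTIC_PARAMS = {"r": 0.5, "K": 100.0, "P0": 1.0}


def _model(seed=0, r=1.0, K=50.0, trainable=True):
    system = logistic_system()
    params = TrainableODEParameters(system, {"r": r, "K": K},
                                    trainable=trainable,
                                    scales={"r": 1.0, "K": 100.0})
    spec = NetworkSpec(hidden_layers=2, neurons=16, output_dim=1,
                       input_scale=100.0, output_scale=100.0)
    return PinnModel(system, spec, params, seed=seed)


def _small_problem(seed=0, n_obs=20, n_colloc=30, sigma=0.0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 100, n_obs)
    clean = logistic_analytic(t, LOGISTIC_PARAMS)
    obs = ObservationSet(times=t, values=clean + sigma * rng.normal(size=n_obs),
                         noise_sigma=sigma, seed=seed)
    colloc = sample_collocation(n_colloc, 0.0, 100.0, seed=seed)
    return obs, colloc


class TestTrain:
    def test_single_iteration_logs_one_row(self):
        obs, colloc = _small_problem()
        history = train(_model(), obs, colloc,
                        TrainingConfig(iterations=1, log_every=100),
                        ic=np.array([1.0]))
        assert len(history) == 1
        assert history.iterations[0] == 1

    def test_zero_iterations_leave_model_untouched(self):
        obs, colloc = _small_problem()
        model = _model(seed=3)
        before = model.predict(np.linspace(0, 100, 7)).copy()
        history = train(model, obs, colloc, TrainingConfig(iterations=0),
                        ic=np.array([1.0]))
        assert len(history) == 0
        np.testing.assert_array_equal(model.predict(np.linspace(0, 100, 7)), before)

    def test_seeded_reruns_are_bit_identical(self):
        histories = []
        for _ in range(2):
            obs, colloc = _small_problem(seed=7, sigma=1.0)
            history = train(_model(seed=7), obs, colloc,
                            TrainingConfig(iterations=120, log_every=20, seed=7),
                            ic=np.array([1.0]))
            histories.append(history)
        a, b = histories
        np.testing.assert_array_equal(a.total, b.total)
        np.testing.assert_array_equal(a.parameter_traces["r"],
                                      b.parameter_traces["r"])
        np.testing.assert_array_equal(a.parameter_traces["K"],
                                      b.parameter_traces["K"])

    def test_logged_totals_equal_component_sums(self):
        obs, colloc = _small_problem(seed=2, sigma=1.0)
        history = train(_model(seed=2), obs, colloc,
                        TrainingConfig(iterations=150, log_every=25),
                        ic=np.array([1.0]))
        recomposed = (1.0 * history.data_loss + 1.0 * history.ic_loss
                      + 1.0 * history.physics_loss)
        np.testing.assert_array_equal(history.total, recomposed)

    def test_best_weights_retained(self):
        # truth-initialized parameters on noiseless data: final loss cannot
        # exceed the loss of any earlier iterate
        obs, colloc = _small_problem(seed=1, sigma=0.0)
        model = _model(seed=1, r=0.5, K=100.0)
        history = train(model, obs, colloc,
                        TrainingConfig(iterations=200, log_every=10),
                        ic=np.array([1.0]))
        from odepinn.losses import data_loss, ic_loss, physics_loss
        final_total = (data_loss(model, obs) + ic_loss(model, 0.0, np.array([1.0]))
                       + physics_loss(model, colloc))
        assert final_total <= history.total[0] + 1e-12
        assert history.best_iteration >= 1

    def test_parameter_traces_move_toward_truth(self):
        obs, colloc = _small_problem(seed=0, n_obs=30, n_colloc=50)
        history = train(_model(seed=0, r=1.0, K=50.0), obs, colloc,
                        TrainingConfig(iterations=2000, log_every=100),
                        ic=np.array([1.0]))
        r_trace = history.parameter_traces["r"]
        assert abs(r_trace[-1] - 0.5) < abs(r_trace[0] - 0.5)

    def test_nothing_to_train_on_rejected(self):
        with pytest.raises(ValueError, match="nothing"):
            train(_model(), None, None, TrainingConfig(iterations=1))


class TestHasConverged:
    def _history(self, totals):
        totals = np.asarray(totals, dtype=float)
        n = len(totals)
        return TrainHistory(iterations=np.arange(1, n + 1),
                            data_loss=totals, ic_loss=np.zeros(n),
                            physics_loss=np.zeros(n), total=totals)

    def test_flat_tail_converged(self):
        assert has_converged(self._history([5.0] * 20), window=10, tol=1e-3)

    def test_halving_loss_not_converged(self):
        totals = 100.0 * 0.5 ** np.arange(20)
        assert not has_converged(self._history(totals), window=10, tol=1e-3)

    def test_boundary_change_is_not_converged(self):
        # relative change exactly equal to tol fails the strict inequality
        tol = 0.5
        totals = [2.0] * 5 + [1.0] * 5  # first-half mean 2, second-half 1
        assert not has_converged(self._history(totals), window=10, tol=tol)
        assert has_converged(self._history(totals), window=10, tol=tol + 1e-12)

    def test_window_exceeding_history_warns_false(self):
        with pytest.warns(UserWarning, match="window"):
            assert not has_converged(self._history([1.0, 1.0]), window=10)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            has_converged(self._history([]))


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = _model(seed=5, r=0.8, K=90.0)
        path = tmp_path / "model.ckpt.json"
        checkpoint(model, path)
        other = _model(seed=99, r=1.0, K=50.0)
        restore(other, path)
        t = np.linspace(0, 100, 23)
        np.testing.assert_array_equal(other.predict(t), model.predict(t))

    def test_restored_ode_parameters_match_saved(self, tmp_path):
        model = _model(seed=5, r=0.8, K=90.0)
        path = tmp_path / "model.ckpt.json"
        checkpoint(model, path)
        other = _model(seed=99)
        restore(other, path)
        assert other.ode_params.current() == pytest.approx(
            {"r": 0.8, "K": 90.0})

    def test_architecture_mismatch_names_field(self, tmp_path):
        model = _model(seed=5)
        path = tmp_path / "model.ckpt.json"
        checkpoint(model, path)
        system = logistic_system()
        params = TrainableODEParameters(system, {"r": 1.0, "K": 50.0})
        bigger = PinnModel(
            system,
            NetworkSpec(hidden_layers=3, neurons=16, output_dim=1,
                        input_scale=100.0, output_scale=100.0),
            params, seed=0)
        with pytest.raises(ValueError, match="hidden_layers"):
            restore(bigger, path)

    def test_non_checkpoint_file_rejected(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text("{}")
        with pytest.raises(ValueError, match="checkpoint"):
            restore(_model(), path)

    def test_periodic_checkpointing_during_training(self, tmp_path):
        obs, colloc = _small_problem()
        path = tmp_path / "train.ckpt.json"
        config = TrainingConfig(iterations=10, checkpoint_every=5,
                                checkpoint_path=str(path))
        train(_model(), obs, colloc, config, ic=np.array([1.0]))
        assert path.exists()


class TestTrainingConfig:
    def test_invalid_learning_rate_rejected(self):
        with pytest.raises(ValueError, match="learning_rate"):
            TrainingConfig(iterations=10, learning_rate=0.0)

    def test_negative_iterations_rejected(self):
        with pytest.raises(ValueError, match="iterations"):
            TrainingConfig(iterations=-1)

    def test_unsupported_optimizer_rejected(self):
        with pytest.raises(ValueError, match="optimizer"):
            TrainingConfig(iterations=10, optimizer="lbfgs")
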