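"""Network forward/derivative passes and the three loss components."""

import numpy as np
import pytest

from odepinn import (
    CollocationSet,
    LossBreakdown,
    NetworkSpec,
    ObservationSet,
    PinnModel,
    TrainableODEParameters,
    data_loss,
    gene_binding_system,
    ic_loss,
    logistic_analytic,
    logistic_rhs,
    logistic_system,
    physics_loss,
    sample_collocation,
    total_loss,
)
from odepinn.autodiff import Tensor
from odepinn.network import MLP


def _logistic_model(seed=0, **spec_kwargs) -> PinnModel:
    system = logistic_system()
    defaults = dict(hidden_layers=3, neurons=50, output_dim=1,
                    input_scale=100.0, output_scale=100.0)
    defaults.update(spec_kwargs)
    params = TrainableODEParameters(system, {"r": 0.5, "K": 100.0},
                                    trainable=True, scales={"K": 100.0})
    return PinnModel(system, NetworkSpec(**defaults), params, seed=seed)


def _zero_weights_with_bias(net: MLP, bias_value: float):
    weights = [np.zeros_like(w) for w in net.copy_weights()]
    weights[-1] = np.full_like(weights[-1], bias_value)
    net.load_weights(weights)


class TestPredict:
    def test_constant_network_outputs_transformed_bias(self):
        model = _logistic_model()
        _zero_weights_with_bias(model.net, 0.25)
        pred = model.predict(np.linspace(0, 100, 9))
        # output transform is an affine scale by 100
        np.testing.assert_allclose(pred, 25.0)

    def test_same_weights_same_output(self):
        model = _logistic_model(seed=4)
        t = np.linspace(0, 100, 17)
        np.testing.assert_array_equal(model.predict(t), model.predict(t))

    def test_outputs_finite_everywhere(self):
        model = _logistic_model(seed=2)
        t = np.array([-1e4, -1.0, 0.0, 50.0, 1e4])
        assert np.all(np.isfinite(model.predict(t)))

    def test_empty_input_gives_empty_matrix(self):
        model = _logistic_model()
        assert model.predict(np.empty(0)).shape == (0, 1)

    def test_identical_seeds_build_identical_networks(self):
        a, b = _logistic_model(seed=11), _logistic_model(seed=11)
        t = np.linspace(0, 100, 13)
        np.testing.assert_array_equal(a.predict(t), b.predict(t))


class TestTimeDerivative:
    def test_constant_network_has_zero_derivative(self):
        model = _logistic_model()
        _zero_weights_with_bias(model.net, 0.7)
        np.testing.assert_allclose(model.time_derivative(np.linspace(0, 100, 5)),
                                   0.0, atol=1e-14)

    def test_single_tanh_unit_derivative_at_origin(self):
        # f(t) = tanh(t): f'(0) = sech^2(0) = 1
        system = logistic_system()
        params = TrainableODEParameters(system, {"r": 0.5, "K": 100.0},
                                        trainable=False)
        spec = NetworkSpec(hidden_layers=1, neurons=1, output_dim=1,
                           input_scale=1.0, output_transform="identity")
        model = PinnModel(system, spec, params, seed=0)
        model.net.load_weights([np.array([[1.0]]), np.array([0.0]),
                                np.array([[1.0]]), np.array([0.0])])
        assert model.predict(np.array([0.5]))[0, 0] == pytest.approx(np.tanh(0.5))
        assert model.time_derivative(np.array([0.0]))[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("transform", ["scale", "identity", "softplus"])
    def test_matches_central_finite_differences(self, transform):
        model = _logistic_model(seed=5, output_transform=transform,
                                output_scale=100.0 if transform != "identity" else 1.0)
        t = np.linspace(1.0, 99.0, 25)
        h = 1e-4
        fd = (model.predict(t + h) - model.predict(t - h)) / (2 * h)
        ad = model.time_derivative(t)
        scale = np.maximum(np.abs(fd), 1.0)
        assert np.max(np.abs(ad - fd) / scale) < 1e-4

    def test_derivative_scales_linearly_with_output_transform(self):
        base = _logistic_model(seed=3, output_scale=1.0)
        scaled = _logistic_model(seed=3, output_scale=100.0)
        scaled.net.load_weights(base.net.copy_weights())
        t = np.linspace(0, 100, 21)
        np.testing.assert_allclose(scaled.time_derivative(t),
                                   100.0 * base.time_derivative(t), rtol=1e-12)


class _ClosedFormNet:
    """Stub network returning the exact logistic solution and its rate."""

    def __init__(self, params):
        self.params = params

    def forward_with_tangent(self, t):
        t = np.asarray(t, dtype=float).reshape(-1, 1)
        P = logistic_analytic(t, self.params)
        return Tensor(P), Tensor(logistic_rhs(P, self.params))


class TestPhysicsLoss:
    def test_exact_solution_has_negligible_residual(self):
        model = _logistic_model()
        model.net = _ClosedFormNet({"r": 0.5, "K": 100.0, "P0": 1.0})
        colloc = sample_collocation(200, 0.0, 100.0, seed=1)
        assert physics_loss(model, colloc) < 1e-8

    def test_single_point_equals_squared_residual(self):
        model = _logistic_model(seed=6)
        t = np.array([42.0])
        value = physics_loss(model, CollocationSet(times=t))
        du = model.time_derivative(t)[0, 0]
        P = model.predict(t)[0, 0]
        residual = du - logistic_rhs(P, {"r": 0.5, "K": 100.0})
        assert value == pytest.approx(residual**2, rel=1e-12)

    def test_nonnegative_for_random_models(self):
        for seed in range(3):
            model = _logistic_model(seed=seed)
            assert physics_loss(model, sample_collocation(50, 0, 100, seed)) >= 0

    def test_empty_collocation_rejected(self):
        model = _logistic_model()
        with pytest.raises(ValueError, match="[Cc]olloc"):
            physics_loss(model, CollocationSet(times=np.empty(0)))

    def test_autodiff_and_finite_difference_routes_agree(self):
        # same residual computed with the exact derivative and a 4th-order
        # central difference of the prediction
        model = _logistic_model(seed=9)
        colloc = sample_collocation(100, 1.0, 99.0, seed=2)
        auto = physics_loss(model, colloc)
        t = colloc.times
        h = 1e-2
        fd = (-model.predict(t + 2 * h) + 8 * model.predict(t + h)
              - 8 * model.predict(t - h) + model.predict(t - 2 * h)) / (12 * h)
        P = model.predict(t)
        resid = fd[:, 0] - logistic_rhs(P[:, 0], {"r": 0.5, "K": 100.0})
        assert np.mean(resid**2) == pytest.approx(auto, abs=1e-6)


class TestDataAndIcLoss:
    def test_zero_when_predictions_match(self):
        model = _logistic_model(seed=1)
        t = np.linspace(0, 100, 15)
        obs = ObservationSet(times=t, values=model.predict(t))
        assert data_loss(model, obs) == 0.0

    def test_constant_offset_gives_squared_offset(self):
        model = _logistic_model(seed=1)
        t = np.linspace(0, 100, 20)
        obs = ObservationSet(times=t, values=model.predict(t) + 3.0)
        assert data_loss(model, obs) == pytest.approx(9.0, rel=1e-12)

    def test_matches_naive_two_loop_mse(self, rng):
        model = _logistic_model(seed=8)
        t = np.linspace(0, 100, 13)
        values = rng.normal(50, 10, size=(13, 1))
        obs = ObservationSet(times=t, values=values)
        pred = model.predict(t)
        acc = 0.0
        for i in range(13):
            for j in range(1):
                acc += (pred[i, j] - values[i, j]) ** 2
        assert data_loss(model, obs) == pytest.approx(acc / 13, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        model = _logistic_model()
        obs = ObservationSet(times=np.array([0.0, 1.0]), values=np.ones((2, 3)))
        with pytest.raises(ValueError, match="dim"):
            data_loss(model, obs)

    def test_ic_loss_squared_deviation(self):
        model = _logistic_model()
        _zero_weights_with_bias(model.net, 0.03)  # predict(0) = 3
        assert ic_loss(model, 0.0, np.array([1.0])) == pytest.approx(4.0)

    def test_gene_ic_exact_match_is_zero(self):
        system = gene_binding_system()
        params = TrainableODEParameters(
            system, {"k_on": 1 / 60, "k_off": 0.5 / 60}, trainable=False)
        spec = NetworkSpec(hidden_layers=2, neurons=8, output_dim=3,
                           input_scale=100.0, output_transform="identity")
        model = PinnModel(system, spec, params, seed=0)
        ic = model.predict(np.array([0.0]))[0]
        assert ic_loss(model, 0.0, ic) == pytest.approx(0.0, abs=1e-28)


class TestTotalLoss:
    def test_default_weights_sum(self):
        parts = LossBreakdown(1.0, 2.0, 3.0)
        assert total_loss(parts) == 6.0
        assert parts.total == 6.0

    def test_single_component_passthrough(self):
        assert total_loss(LossBreakdown(0.0, 5.0, 0.0)) == 5.0

    def test_custom_weights(self):
        assert total_loss(LossBreakdown(1.0, 5.0, 4.0), weights=(2, 0, 1)) == 6.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            total_loss(LossBreakdown(1.0, 1.0, 1.0), weights=(-1, 1, 1))
        with pytest.raises(ValueError, match="weights"):
            LossBreakdown(1.0, 1.0, 1.0, weights=(-1, 1, 1))

    def test_decomposition_identity_on_random_components(self, rng):
        for _ in range(20):
            d, i, p = rng.uniform(0, 10, 3)
            assert total_loss(LossBreakdown(d, i, p)) == d * 1.0 + i * 1.0 + p * 1.0


class TestSpecValidation:
    def test_non_smooth_activation_rejected(self):
        with pytest.raises(ValueError, match="smooth"):
            NetworkSpec(activation="relu")

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError, match="transform"):
            NetworkSpec(output_transform="exp")

    def test_parameter_schema_enforced(self):
        system = logistic_system()
        with pytest.raises(ValueError, match="schema"):
            TrainableODEParameters(system, {"r": 0.5, "K": 100.0, "zz": 1.0})
        with pytest.raises(ValueError, match="missing"):
            TrainableODEParameters(system, {"r": 0.5})
        with pytest.raises(ValueError, match="positive"):
            TrainableODEParameters(system, {"r": 0.5, "K": -3.0})
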