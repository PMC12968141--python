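"""Scikit-learn style estimators for physics-informed ODE regression.

:class:`PINNRegressor` fits a tanh network to (time, state) observations
while penalizing the residual of a governing ODE system at collocation
points; ODE parameters flagged trainable are estimated jointly with the
network (the inverse problem).  :class:`TimeSeriesNNRegressor` is the
physics-free baseline: the same network trained on the data loss alone.

Both follow sklearn conventions — constructor stores hyperparameters
untouched, ``fit`` validates and learns, fitted attributes carry a trailing
underscore — and compose with :func:`sklearn.base.clone` and model
selection utilities.
"""

from __future__ import annotations

from numbers import Integral

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import CollocationSet, ObservationSet, sample_collocation
from .network import MLP, NetworkSpec, PinnModel, TrainableODEParameters
from .ode_models import ODESystem, gene_binding_system, logistic_system
from .training import TrainingConfig, train

__all__ = ["PINNRegressor", "TimeSeriesNNRegressor"]

_SYSTEMS = {"logistic": logistic_system, "gene": gene_binding_system}


def _resolve_system(system) -> ODESystem:
    if isinstance(system, ODESystem):
        return system
    if isinstance(system, str):
        try:
            return _SYSTEMS[system]()
        except KeyError:
            raise ValueError(
                f"unknown system {system!r}; choose from {sorted(_SYSTEMS)} "
                "or pass an ODESystem") from None
    raise TypeError(f"system must be a name or ODESystem, got {type(system)}")


def _check_t_y(t, y, dim):
    t = np.asarray(t, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape != (t.shape[0], dim):
        raise ValueError(f"y must have shape ({t.shape[0]}, {dim}), got {y.shape}")
    return t, y


class PINNRegressor(RegressorMixin, BaseEstimator):
    """Physics-informed regression on a first-order ODE system.

    Parameters
    ----------
    system : str or ODESystem, default="logistic"
        The governing system ("logistic", "gene", or a custom ODESystem).
    param_init : dict, optional
        Initial values for every ODE parameter.  Parameters listed in
        `trainable_params` are optimized; the rest stay fixed.  ``None``
        entries are drawn uniformly on `param_init_range` at fit time.
    trainable_params : iterable of str, bool, default=True
        Which ODE parameters to estimate; ``True`` means all, ``False``
        none (forward problem).
    param_scales : dict, optional
        Per-parameter conditioning scales (the optimizer works on
        value/scale); defaults to 1 for every parameter.
    ic : array-like, optional
        Initial state at `t0`; enables the initial-condition loss.
    collocation : int or CollocationSet, default=200
        Residual-enforcement points; an int draws that many uniformly over
        `t_domain` with `seed`.
    t_domain : (float, float), default=(0, 100)
        Time domain for collocation sampling.
    hidden_layers, neurons : int
        Architecture of the tanh trunk (defaults 3 x 50).
    input_scale, output_scale : float, optional
        Feature/output conditioning; default to the domain width and 1.
    output_transform : {"scale", "identity", "softplus"}
    n_iterations : int, default=20000
        Full-batch Adam steps.
    learning_rate : float, default=1e-3
    loss_weights : triple, default=(1, 1, 1)
        Weights of (data, initial-condition, physics) losses.
    log_every : int, default=100
    seed : int, default=0
        Controls weight initialization, collocation sampling and random
        parameter initial guesses.

    Attributes
    ----------
    params_ : dict
        Final ODE parameter estimates (all parameters, fixed ones included).
    history_ : TrainHistory
        Logged loss components and parameter traces.
    model_ : PinnModel
        The trained network bound to the system.
    """

    def __init__(self, system="logistic", param_init=None, trainable_params=True,
                 param_scales=None, ic=None, t0=0.0, collocation=200,
                 t_domain=(0.0, 100.0), hidden_layers=3, neurons=50,
                 input_scale=None, output_scale=1.0, output_transform="scale",
                 n_iterations=20000, learning_rate=1e-3,
                 loss_weights=(1.0, 1.0, 1.0), log_every=100, seed=0,
                 param_init_range=(0.0, 0.1)):
        self.system = system
        self.param_init = param_init
        self.trainable_params = trainable_params
        self.param_scales = param_scales
        self.ic = ic
        self.t0 = t0
        self.collocation = collocation
        self.t_domain = t_domain
        self.hidden_layers = hidden_layers
        self.neurons = neurons
        self.input_scale = input_scale
        self.output_scale = output_scale
        self.output_transform = output_transform
        self.n_iterations = n_iterations
        self.learning_rate = learning_rate
        self.loss_weights = loss_weights
        self.log_every = log_every
        self.seed = seed
        self.param_init_range = param_init_range

    # -- fitting --------------------------------------------------------------
    def _build(self, rng: np.random.Generator) -> PinnModel:
        system = _resolve_system(self.system)
        init = dict(self.param_init or {})
        missing = [n for n in system.param_names() if init.get(n) is None]
        lo, hi = self.param_init_range
        for name in missing:
            init[name] = float(rng.uniform(lo, hi))
        input_scale = (self.input_scale if self.input_scale is not None
                       else self.t_domain[1] - self.t_domain[0])
        spec = NetworkSpec(
            hidden_layers=self.hidden_layers, neurons=self.neurons,
            output_dim=system.dim, input_scale=input_scale,
            output_scale=self.output_scale,
            output_transform=self.output_transform,
        )
        params = TrainableODEParameters(
            system, init, trainable=self.trainable_params,
            scales=self.param_scales)
        return PinnModel(system, spec, params, seed=self.seed)

    def fit(self, t, y=None):
        """Fit to observations (t, y); `y` may be None for a pure forward
        solve driven by the initial condition and physics alone."""
        if not isinstance(self.n_iterations, Integral) or self.n_iterations < 0:
            raise ValueError(f"n_iterations must be a nonnegative int, "
                             f"got {self.n_iterations}")
        rng = np.random.default_rng(self.seed)
        model = self._build(rng)
        obs = None
        if y is not None:
            t_arr, y_arr = _check_t_y(t, y, model.system.dim)
            obs = ObservationSet(times=t_arr, values=y_arr)
        if isinstance(self.collocation, CollocationSet):
            colloc = self.collocation
        elif self.collocation:
            colloc = sample_collocation(
                int(self.collocation), self.t_domain[0], self.t_domain[1],
                seed=self.seed)
        else:
            colloc = None
        ic = None if self.ic is None else np.atleast_1d(
            np.asarray(self.ic, dtype=float))
        config = TrainingConfig(
            iterations=int(self.n_iterations),
            learning_rate=self.learning_rate,
            log_every=self.log_every, seed=self.seed,
            loss_weights=tuple(self.loss_weights),
        )
        self.history_ = train(model, obs, colloc, config, ic=ic, t0=self.t0)
        self.model_ = model
        self.params_ = model.ode_params.current()
        self.n_features_in_ = 1
        return self

    def predict(self, t):
        """Predicted state matrix, shape (len(t), dim); 1-d for 1-state
        systems to match the sklearn regressor contract."""
        check_is_fitted(self, "model_")
        out = self.model_.predict(np.asarray(t, dtype=float).reshape(-1))
        return out[:, 0] if out.shape[1] == 1 else out

    def time_derivative(self, t):
        check_is_fitted(self, "model_")
        return self.model_.time_derivative(np.asarray(t, dtype=float).reshape(-1))


class TimeSeriesNNRegressor(RegressorMixin, BaseEstimator):
    """Plain feed-forward regression of state on time (no physics).

    The data-only baseline against which the physics-informed fit is
    compared: identical architecture and optimizer, objective reduced to
    the mean squared error on the observations.
    """

    def __init__(self, hidden_layers=3, neurons=50, output_dim=1,
                 input_scale=100.0, output_scale=1.0, output_transform="scale",
                 n_iterations=20000, learning_rate=1e-3, log_every=100, seed=0):
        self.hidden_layers = hidden_layers
        self.neurons = neurons
        self.output_dim = output_dim
        self.input_scale = input_scale
        self.output_scale = output_scale
        self.output_transform = output_transform
        self.n_iterations = n_iterations
        self.learning_rate = learning_rate
        self.log_every = log_every
        self.seed = seed

    def fit(self, t, y):
        from .autodiff import mse
        from .optim import Adam

        t_arr, y_arr = _check_t_y(t, y, self.output_dim)
        spec = NetworkSpec(
            hidden_layers=self.hidden_layers, neurons=self.neurons,
            output_dim=self.output_dim, input_scale=self.input_scale,
            output_scale=self.output_scale,
            output_transform=self.output_transform,
        )
        net = MLP(spec, seed=self.seed)
        opt = Adam(net.params, lr=self.learning_rate)
        logged_it, logged = [], []
        best = (np.inf, None)
        for it in range(1, int(self.n_iterations) + 1):
            loss = mse(net.forward(t_arr), y_arr)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(f"non-finite data loss at iteration {it}")
            if value < best[0]:
                best = (value, net.copy_weights())
            if it % self.log_every == 0 or it == self.n_iterations:
                logged_it.append(it)
                logged.append(value)
            opt.zero_grad()
            loss.backward()
            opt.step()
        if best[1] is not None:
            net.load_weights(best[1])
        self.net_ = net
        self.loss_history_ = (np.asarray(logged_it), np.asarray(logged))
        self.n_features_in_ = 1
        return self

    def predict(self, t):
        check_is_fitted(self, "net_")
        t = np.asarray(t, dtype=float).reshape(-1)
        if t.size == 0:
            return np.empty((0, self.output_dim))
        out = self.net_.forward(t).numpy()
        return out[:, 0] if out.shape[1] == 1 else out
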