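"""The network approximator and its exact time derivative.

A :class:`PinnModel` maps time to the ODE state through a fully connected
tanh network.  Besides the plain forward pass it propagates a forward-mode
tangent through every layer, yielding the exact derivative of the output
with respect to time — the quantity the physics residual compares against
the ODE right-hand side.  Because the tangent pass is itself built from
autodiff ops, reverse mode through it gives the gradients of the physics
loss with respect to the weights and the trainable ODE parameters.

Input and output scaling keep the tanh trunk on O(1) values: time is divided
by ``input_scale`` (normally the domain width) and the raw output multiplied
by ``output_scale`` (normally the expected state magnitude).  An optional
softplus output transform constrains states to be nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .autodiff import Tensor, dtanh_mul, linear, sigmoid, softplus, tanh
from .ode_models import ODESystem

__all__ = ["NetworkSpec", "TrainableODEParameters", "MLP", "PinnModel"]

_ACTIVATIONS = {"tanh"}


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the time-to-state network.

    ``output_transform`` is one of ``"identity"``, ``"scale"`` (multiply by
    ``output_scale``) or ``"softplus"`` (scaled softplus, for nonnegative
    concentrations); every choice is smooth, as the physics residual
    requires.
    """

    hidden_layers: int = 3
    neurons: int = 50
    activation: str = "tanh"
    output_dim: int = 1
    input_scale: float = 1.0
    output_transform: str = "scale"
    output_scale: float = 1.0

    def __post_init__(self):
        if self.hidden_layers < 1 or self.neurons < 1 or self.output_dim < 1:
            raise ValueError("layer counts and dimensions must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(
                f"activation {self.activation!r} is not smooth/supported; "
                f"choose from {sorted(_ACTIVATIONS)}")
        if self.output_transform not in ("identity", "scale", "softplus"):
            raise ValueError(
                f"unknown output transform {self.output_transform!r}")
        if self.input_scale <= 0 or self.output_scale <= 0:
            raise ValueError("input_scale and output_scale must be positive")

    def layer_sizes(self) -> list[int]:
        return [1] + [self.neurons] * self.hidden_layers + [self.output_dim]

    def as_dict(self) -> dict:
        return {
            "hidden_layers": self.hidden_layers, "neurons": self.neurons,
            "activation": self.activation, "output_dim": self.output_dim,
            "input_scale": self.input_scale,
            "output_transform": self.output_transform,
            "output_scale": self.output_scale,
        }


class TrainableODEParameters:
    """Named ODE parameters, optionally optimized jointly with the network.

    Each parameter is stored as an internal variable ``v`` with the physical
    value ``scale * v``; choosing ``scale`` near the parameter's expected
    magnitude keeps Adam's per-step movement proportionate for parameters of
    very different sizes (e.g. a carrying capacity of order 100 next to a
    binding rate of order 0.02).  Positivity constraints from the system
    schema are checked on the supplied values, not enforced by transform.
    """

    def __init__(
        self,
        system: ODESystem,
        values: Mapping[str, float],
        trainable: Iterable[str] | bool = True,
        scales: Mapping[str, float] | None = None,
    ):
        schema_names = set(system.param_names())
        unknown = set(values) - schema_names
        if unknown:
            raise ValueError(
                f"parameters {sorted(unknown)} not in the schema of "
                f"system {system.name!r} ({sorted(schema_names)})")
        missing = schema_names - set(values)
        if missing:
            raise ValueError(f"missing initial values for {sorted(missing)}")
        system.validate_params(values)
        if trainable is True:
            trainable_set = set(schema_names)
        elif trainable is False:
            trainable_set = set()
        else:
            trainable_set = set(trainable)
            if trainable_set - schema_names:
                raise ValueError(
                    f"trainable names {sorted(trainable_set - schema_names)} "
                    f"not in schema")
        scales = dict(scales or {})
        self.system = system
        self.names: tuple[str, ...] = system.param_names()
        self.trainable: frozenset[str] = frozenset(trainable_set)
        self._scales = {n: float(scales.get(n, 1.0)) for n in self.names}
        self._raw = {
            n: Tensor(float(values[n]) / self._scales[n],
                      requires_grad=(n in trainable_set))
            for n in self.names
        }

    @property
    def scales(self) -> dict[str, float]:
        return dict(self._scales)

    def tensors(self) -> dict[str, Tensor]:
        """Physical-value tensors (scale * raw), rebuilt per training step."""
        return {n: self._raw[n] * self._scales[n] for n in self.names}

    def current(self) -> dict[str, float]:
        return {n: float(self._raw[n].data) * self._scales[n] for n in self.names}

    def trainable_tensors(self) -> list[Tensor]:
        return [self._raw[n] for n in self.names if n in self.trainable]

    def set_value(self, name: str, value: float) -> None:
        self._raw[name].data = np.asarray(float(value) / self._scales[name])

    def state_dict(self) -> dict:
        return {"values": self.current(), "scales": self._scales,
                "trainable": sorted(self.trainable)}


def _glorot_layers(sizes: list[int], rng: np.random.Generator) -> list[Tensor]:
    params: list[Tensor] = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        params.append(Tensor(rng.uniform(-limit, limit, (fan_in, fan_out)),
                             requires_grad=True))
        params.append(Tensor(np.zeros(fan_out), requires_grad=True))
    return params


class MLP:
    """Fully connected tanh network with Glorot-uniform initialization."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.params: list[Tensor] = _glorot_layers(spec.layer_sizes(), rng)

    def _trunk(self, t_col: Tensor) -> Tensor:
        a = t_col * (1.0 / self.spec.input_scale)
        p = self.params
        for i in range(0, len(p) - 2, 2):
            a = tanh(linear(a, p[i], p[i + 1]))
        return linear(a, p[-2], p[-1])

    def _trunk_with_tangent(self, t_col: Tensor) -> tuple[Tensor, Tensor]:
        inv = 1.0 / self.spec.input_scale
        a = t_col * inv
        da = Tensor(np.full(t_col.shape, inv))
        p = self.params
        for i in range(0, len(p) - 2, 2):
            z = linear(a, p[i], p[i + 1])
            dz = linear(da, p[i])
            a = tanh(z)
            da = dtanh_mul(a, dz)
        return linear(a, p[-2], p[-1]), linear(da, p[-2])

    def _transform(self, u: Tensor) -> Tensor:
        s = self.spec
        if s.output_transform == "identity":
            return u
        if s.output_transform == "scale":
            return u * s.output_scale
        return softplus(u) * s.output_scale

    def _transform_with_tangent(self, u: Tensor, du: Tensor) -> tuple[Tensor, Tensor]:
        s = self.spec
        if s.output_transform == "identity":
            return u, du
        if s.output_transform == "scale":
            return u * s.output_scale, du * s.output_scale
        return softplus(u) * s.output_scale, sigmoid(u) * du * s.output_scale

    def forward(self, t: np.ndarray | Tensor) -> Tensor:
        t_col = _as_column(t)
        return self._transform(self._trunk(t_col))

    def forward_with_tangent(self, t: np.ndarray | Tensor) -> tuple[Tensor, Tensor]:
        t_col = _as_column(t)
        return self._transform_with_tangent(*self._trunk_with_tangent(t_col))

    def copy_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != len(self.params):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(self.params, weights):
            if p.data.shape != np.asarray(w).shape:
                raise ValueError("weight shapes do not match the architecture")
            p.data = np.asarray(w, dtype=float).copy()


def _as_column(t) -> Tensor:
    if isinstance(t, Tensor):
        return t
    t = np.asarray(t, dtype=float)
    if t.ndim == 0:
        t = t[None]
    if t.ndim == 1:
        t = t[:, None]
    return Tensor(t)


class PinnModel:
    """Network approximator bound to an ODE system and its parameters."""

    def __init__(
        self,
        system: ODESystem,
        spec: NetworkSpec,
        ode_params: TrainableODEParameters,
        seed: int = 0,
    ):
        if spec.output_dim != system.dim:
            raise ValueError(
                f"network output_dim={spec.output_dim} but system "
                f"{system.name!r} has dim={system.dim}")
        if ode_params.system.name != system.name:
            raise ValueError("ode_params bound to a different system")
        self.system = system
        self.spec = spec
        self.ode_params = ode_params
        self.net = MLP(spec, seed=seed)
        self.seed = int(seed)

    # numpy-facing surface --------------------------------------------------
    def predict(self, t: np.ndarray) -> np.ndarray:
        """State matrix len(t) x dim; empty input yields an empty matrix."""
        t = np.asarray(t, dtype=float)
        if t.size == 0:
            return np.empty((0, self.system.dim))
        return self.net.forward(t).numpy()

    def time_derivative(self, t: np.ndarray) -> np.ndarray:
        """Exact d(predict)/dt via the forward-tangent pass."""
        t = np.asarray(t, dtype=float)
        if t.size == 0:
            return np.empty((0, self.system.dim))
        _, du = self.net.forward_with_tangent(t)
        return du.numpy()

    # training-facing surface ------------------------------------------------
    def trainable_tensors(self) -> list[Tensor]:
        return self.net.params + self.ode_params.trainable_tensors()

    def state_dict(self) -> dict:
        return {
            "format": "odepinn-checkpoint",
            "version": 1,
            "system": self.system.name,
            "seed": self.seed,
            "spec": self.spec.as_dict(),
            "weights": [w.tolist() for w in self.net.copy_weights()],
            "ode_params": self.ode_params.state_dict(),
        }
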