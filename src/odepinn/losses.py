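"""The three loss components of physics-informed training.

* data loss — mean squared error between predictions and observations;
* initial-condition loss — squared deviation of the prediction at t0 from
  the prescribed initial state;
* physics loss — mean squared ODE residual at the collocation points, using
  the network's exact time derivative.

The total is their weighted sum; by default all three weigh equally.  Each
function has a tensor variant (used inside the training graph) and a float
wrapper matching it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, mse
from .datasets import CollocationSet, ObservationSet
from .network import PinnModel

__all__ = ["LossBreakdown", "data_loss", "ic_loss", "physics_loss", "total_loss"]

DEFAULT_WEIGHTS = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class LossBreakdown:
    """Per-component loss values and their weighted total."""

    data_loss: float
    ic_loss: float
    physics_loss: float
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    total: float = None  # type: ignore[assignment]

    def __post_init__(self):
        parts = (self.data_loss, self.ic_loss, self.physics_loss)
        if any(w < 0 for w in self.weights):
            raise ValueError(f"loss weights must be >= 0, got {self.weights}")
        if not all(np.isfinite(parts)):
            raise ValueError(f"non-finite loss components: {parts}")
        if any(p < 0 for p in parts):
            raise ValueError(f"loss components must be >= 0, got {parts}")
        if self.total is None:
            object.__setattr__(
                self, "total",
                sum(w * p for w, p in zip(self.weights, parts)))


def _loss_tensors(
    model: PinnModel,
    obs: ObservationSet | None,
    colloc: CollocationSet | None,
    ic: np.ndarray | None,
    t0: float,
) -> tuple[Tensor | float, Tensor | float, Tensor | float]:
    """Build the three component tensors of one training step."""
    d = data_loss_tensor(model, obs) if obs is not None else 0.0
    i = ic_loss_tensor(model, t0, ic) if ic is not None else 0.0
    p = physics_loss_tensor(model, colloc) if colloc is not None else 0.0
    return d, i, p


# -- tensor variants (differentiable) -----------------------------------------

def data_loss_tensor(model: PinnModel, obs: ObservationSet) -> Tensor:
    if len(obs) == 0:
        raise ValueError("observation set is empty")
    if obs.dim != model.system.dim:
        raise ValueError(
            f"observations have dim={obs.dim}, system has dim={model.system.dim}")
    pred = model.net.forward(obs.times)
    return mse(pred, obs.values)


def ic_loss_tensor(model: PinnModel, t0: float, ic: np.ndarray) -> Tensor:
    ic = np.atleast_1d(np.asarray(ic, dtype=float))
    if ic.shape != (model.system.dim,):
        raise ValueError(
            f"ic must have length {model.system.dim}, got {ic.shape}")
    pred = model.net.forward(np.array([t0]))
    return mse(pred, ic[None, :])


def physics_loss_tensor(model: PinnModel, colloc: CollocationSet) -> Tensor:
    if len(colloc) == 0:
        raise ValueError("collocation set is empty: cannot enforce physics")
    u, du = model.net.forward_with_tangent(colloc.times)
    params = model.ode_params.tensors()
    dim = model.system.dim
    state_cols = [u[:, j:j + 1] for j in range(dim)] if dim > 1 else [u]
    rhs_cols = model.system.rhs(state_cols, colloc.times[:, None], params)
    if len(rhs_cols) != dim:
        raise ValueError(
            f"rhs returned {len(rhs_cols)} components for dim={dim}")
    if dim == 1:
        return mse(du, rhs_cols[0])
    acc = mse(du[:, 0:1], rhs_cols[0])
    for j in range(1, dim):
        acc = acc + mse(du[:, j:j + 1], rhs_cols[j])
    return acc * (1.0 / dim)


# -- float wrappers -----------------------------------------------------------

def data_loss(model: PinnModel, obs: ObservationSet) -> float:
    """Mean squared error between predictions and observed values."""
    return data_loss_tensor(model, obs).item()


def ic_loss(model: PinnModel, t0: float, ic: np.ndarray) -> float:
    """Mean squared deviation of the prediction at t0 from the initial state."""
    return ic_loss_tensor(model, t0, ic).item()


def physics_loss(model: PinnModel, colloc: CollocationSet) -> float:
    """Mean squared ODE residual over collocation points and states."""
    return physics_loss_tensor(model, colloc).item()


def total_loss(parts: LossBreakdown,
               weights: tuple[float, float, float] | None = None) -> float:
    """Weighted sum of the components; default weights are (1, 1, 1)."""
    w = DEFAULT_WEIGHTS if weights is None else tuple(weights)
    if any(x < 0 for x in w):
        raise ValueError(f"loss weights must be >= 0, got {w}")
    return (w[0] * parts.data_loss + w[1] * parts.ic_loss
            + w[2] * parts.physics_loss)
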