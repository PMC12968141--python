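"""Full-batch training loop with loss history, parameter traces and
checkpointing.

Every iteration evaluates the three loss components on all observations and
collocation points (these problems have at most a few hundred of each, so
batching would only add variance), backpropagates the weighted total, and
takes one Adam step over the network weights and any trainable ODE
parameters.  The loop is deterministic given its inputs: identical
configuration and data reproduce bit-identical histories.

The best-so-far weights (lowest total loss) are restored into the model when
training finishes.  Convergence monitoring is diagnostic only — training
always runs the configured number of iterations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .autodiff import Tensor
from .datasets import CollocationSet, ObservationSet
from .losses import DEFAULT_WEIGHTS, LossBreakdown, _loss_tensors
from .network import PinnModel
from .optim import Adam

__all__ = [
    "TrainingConfig", "TrainHistory", "train", "has_converged",
    "checkpoint", "restore",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer settings for one training run.

    ``log_every`` controls the history resolution; the final iteration is
    always logged.  ``checkpoint_every`` only takes effect when a
    ``checkpoint_path`` is supplied.
    """

    iterations: int
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    log_every: int = 100
    checkpoint_every: int = 1000
    seed: int = 0
    loss_weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError(f"iterations must be >= 0, got {self.iterations}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError(f"loss weights must be >= 0, got {self.loss_weights}")


@dataclass
class TrainHistory:
    """Logged loss components and ODE-parameter traces."""

    iterations: np.ndarray
    data_loss: np.ndarray
    ic_loss: np.ndarray
    physics_loss: np.ndarray
    total: np.ndarray
    parameter_traces: dict[str, np.ndarray] = field(default_factory=dict)
    best_iteration: int = 0
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS

    def __len__(self) -> int:
        return len(self.iterations)

    def rows(self) -> list[LossBreakdown]:
        return [
            LossBreakdown(d, i, p, weights=self.weights)
            for d, i, p in zip(self.data_loss, self.ic_loss, self.physics_loss)
        ]

    def final_parameters(self) -> dict[str, float]:
        return {k: float(v[-1]) for k, v in self.parameter_traces.items()}

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "iteration": self.iterations,
            "data_loss": self.data_loss,
            "ic_loss": self.ic_loss,
            "physics_loss": self.physics_loss,
            "total": self.total,
        })
        for name, trace in self.parameter_traces.items():
            frame[name] = trace
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def train(
    model: PinnModel,
    obs: ObservationSet | None,
    colloc: CollocationSet | None,
    config: TrainingConfig,
    ic: np.ndarray | None = None,
    t0: float = 0.0,
) -> TrainHistory:
    """Run ``config.iterations`` Adam steps on the combined loss.

    ``obs`` may be omitted for a purely physics-driven forward solve, and
    ``colloc`` for a pure regression; at least one of the three loss sources
    (observations, initial condition, collocation) must be present.  Raises
    ``RuntimeError`` naming the iteration and component if a loss turns
    non-finite.
    """
    if obs is None and colloc is None and ic is None:
        raise ValueError("nothing to train on: no observations, ic, or collocation")
    tensors = model.trainable_tensors()
    opt = Adam(tensors, lr=config.learning_rate)
    w = config.loss_weights

    logged_it: list[int] = []
    logged: list[tuple[float, float, float, float]] = []
    traces: dict[str, list[float]] = {n: [] for n in model.ode_params.trainable}
    best = (np.inf, -1, None, None)  # total, iteration, weights, ode values

    for it in range(1, config.iterations + 1):
        d, i, p = _loss_tensors(model, obs, colloc, ic, t0)
        total = w[0] * d + w[1] * i + w[2] * p
        dv = d.item() if isinstance(d, Tensor) else d
        iv = i.item() if isinstance(i, Tensor) else i
        pv = p.item() if isinstance(p, Tensor) else p
        tv = total.item() if isinstance(total, Tensor) else float(total)
        if not np.isfinite(tv):
            bad = [name for name, val in
                   (("data", dv), ("ic", iv), ("physics", pv)) if not np.isfinite(val)]
            raise RuntimeError(
                f"non-finite loss at iteration {it}: component(s) {bad} "
                f"(data={dv:.3g}, ic={iv:.3g}, physics={pv:.3g})")
        if tv < best[0]:
            best = (tv, it, model.net.copy_weights(),
                    dict(model.ode_params.current()))
        if it % config.log_every == 0 or it == config.iterations:
            logged_it.append(it)
            logged.append((dv, iv, pv, tv))
            for name in traces:
                traces[name].append(model.ode_params.current()[name])
        if isinstance(total, Tensor):
            opt.zero_grad()
            total.backward()
            opt.step()
        if (config.checkpoint_path is not None
                and it % config.checkpoint_every == 0):
            checkpoint(model, config.checkpoint_path)

    # retain the best weights seen during the run
    if best[2] is not None:
        model.net.load_weights(best[2])
        for name, value in best[3].items():
            model.ode_params.set_value(name, value)
        if config.checkpoint_path is not None:
            checkpoint(model, config.checkpoint_path)

    arr = np.asarray(logged).reshape(-1, 4)  # zero-iteration runs log nothing
    history = TrainHistory(
        iterations=np.asarray(logged_it, dtype=int),
        data_loss=arr[:, 0], ic_loss=arr[:, 1],
        physics_loss=arr[:, 2], total=arr[:, 3],
        parameter_traces={k: np.asarray(v) for k, v in traces.items()},
        best_iteration=best[1],
        weights=w,
    )
    return history


def has_converged(history: TrainHistory, window: int = 10,
                  tol: float = 1e-3) -> bool:
    """Whether the smoothed total loss is flat over the trailing window.

    Compares the mean of the first and second halves of the last `window`
    logged totals; converged iff their relative change is strictly below
    `tol`.  A window longer than the history yields ``False`` with a warning.
    """
    if len(history) == 0:
        raise ValueError("history is empty")
    if window > len(history):
        warnings.warn(
            f"window={window} exceeds history length {len(history)}; "
            "reporting not converged", stacklevel=2)
        return False
    tail = history.total[-window:]
    half = max(1, window // 2)
    first, last = tail[:half].mean(), tail[-half:].mean()
    denom = max(abs(first), 1e-300)
    return bool(abs(first - last) / denom < tol)


def checkpoint(model: PinnModel, path) -> None:
    """Serialize weights, spec and ODE parameters to a JSON container."""
    with open(path, "w") as fh:
        json.dump(model.state_dict(), fh)


def restore(model: PinnModel, path) -> PinnModel:
    """Load a checkpoint into `model`; the architecture must match exactly."""
    with open(path) as fh:
        state = json.load(fh)
    if state.get("format") != "odepinn-checkpoint":
        raise ValueError(f"{path} is not an odepinn checkpoint")
    saved_spec = state["spec"]
    current = model.spec.as_dict()
    for key, value in saved_spec.items():
        if current.get(key) != value:
            raise ValueError(
                f"checkpoint/model architecture mismatch on {key!r}: "
                f"saved {value!r}, model has {current.get(key)!r}")
    if state["system"] != model.system.name:
        raise ValueError(
            f"checkpoint is for system {state['system']!r}, "
            f"model is {model.system.name!r}")
    model.net.load_weights([np.asarray(w) for w in state["weights"]])
    for name, value in state["ode_params"]["values"].items():
        model.ode_params.set_value(name, value)
    return model
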