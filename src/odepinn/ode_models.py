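"""First-order ODE systems, closed-form references, and a numerical oracle.

Two biological systems are built in:

* logistic population growth, ``dP/dt = r P (1 - P/K)``, with its closed-form
  solution ``P(t) = K / (1 + (K/P0 - 1) e^{-rt})``;
* mass-action promoter/transcription-factor binding, where a promoter and a
  transcription factor form a complex at rate ``k_on`` and dissociate at rate
  ``k_off``.  The three states (prom, tf, promtf) obey two conservation laws:
  prom + promtf and tf + promtf are constant.

Right-hand sides are written with plain arithmetic operators so they evaluate
on scalars, numpy arrays, and autodiff tensors alike; :func:`integrate` wraps
an adaptive Dormand–Prince solver as the numerical oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ODESystem", "LogisticParams", "GeneBindingParams", "Trajectory",
    "logistic_rhs", "logistic_analytic", "gene_rhs",
    "logistic_system", "gene_binding_system", "integrate",
    "gene_equilibrium",
]


def _is_numeric(x) -> bool:
    return isinstance(x, (int, float, np.floating, np.ndarray))


@dataclass(frozen=True)
class LogisticParams:
    """Logistic growth parameters: growth rate `r` (1/time), carrying
    capacity `K` and initial population `P0` (population units)."""

    r: float
    K: float
    P0: float

    def __post_init__(self):
        if not math.isfinite(self.r):
            raise ValueError("r must be finite")
        if not self.K > 0:
            raise ValueError(f"carrying capacity K must be positive, got {self.K}")
        if not self.P0 > 0:
            raise ValueError(f"initial population P0 must be positive, got {self.P0}")

    def as_dict(self) -> dict[str, float]:
        return {"r": self.r, "K": self.K}


@dataclass(frozen=True)
class GeneBindingParams:
    """Mass-action binding rates and initial concentrations.

    `k_on` has units 1/(concentration * time), `k_off` 1/time; `ic` holds the
    initial (prom, tf, promtf) concentrations.
    """

    k_on: float
    k_off: float
    ic: tuple[float, float, float] = (17.0, 25.0, 0.0)

    def __post_init__(self):
        if self.k_on < 0:
            raise ValueError(f"binding rate k_on must be >= 0, got {self.k_on}")
        if self.k_off < 0:
            raise ValueError(f"unbinding rate k_off must be >= 0, got {self.k_off}")
        if len(self.ic) != 3 or any(c < 0 for c in self.ic):
            raise ValueError(f"ic must be three nonnegative concentrations, got {self.ic}")
        object.__setattr__(self, "ic", tuple(float(c) for c in self.ic))

    def as_dict(self) -> dict[str, float]:
        return {"k_on": self.k_on, "k_off": self.k_off}


@dataclass(frozen=True)
class ODESystem:
    """A named autonomous first-order ODE system ``dx/dt = f(x, t; theta)``.

    ``rhs`` maps (state columns, time, parameter mapping) to the list of
    per-state derivatives; it must accept scalars, numpy arrays and autodiff
    tensors as state columns.  ``param_schema`` lists (name, must_be_positive)
    pairs; ``analytic``, when available, is the closed-form solution
    ``(t, params) -> states``.
    """

    name: str
    state_names: tuple[str, ...]
    rhs: Callable[[Sequence[Any], Any, Mapping[str, Any]], list]
    param_schema: tuple[tuple[str, bool], ...]
    analytic: Callable[[np.ndarray, Mapping[str, float]], np.ndarray] | None = None

    @property
    def dim(self) -> int:
        return len(self.state_names)

    def param_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.param_schema)

    def validate_params(self, params: Mapping[str, float]) -> None:
        for name, positive in self.param_schema:
            if name not in params:
                raise ValueError(f"missing parameter {name!r} for system {self.name!r}")
            if positive and not params[name] > 0:
                raise ValueError(f"parameter {name!r} must be positive, got {params[name]}")


@dataclass(frozen=True)
class Trajectory:
    """A solution sampled on a strictly increasing time grid."""

    times: np.ndarray
    states: np.ndarray
    state_names: tuple[str, ...] = ()

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if states.ndim == 1:
            states = states[:, None]
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be a strictly increasing 1-d vector")
        if states.shape[0] != times.shape[0]:
            raise ValueError(
                f"states has {states.shape[0]} rows for {times.shape[0]} times")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(states))):
            raise ValueError("trajectory contains non-finite entries")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    def to_frame(self) -> pd.DataFrame:
        names = self.state_names or tuple(f"x{i}" for i in range(self.states.shape[1]))
        frame = pd.DataFrame(self.states, columns=list(names))
        frame.insert(0, "t", self.times)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        frame = pd.read_csv(path)
        if frame.columns[0] != "t":
            raise ValueError(f"first column must be 't', got {frame.columns[0]!r}")
        return cls(
            times=frame["t"].to_numpy(),
            states=frame.iloc[:, 1:].to_numpy(),
            state_names=tuple(frame.columns[1:]),
        )


# -- right-hand sides ---------------------------------------------------------

def logistic_rhs(P, params: LogisticParams | Mapping[str, Any]):
    """Logistic growth rate ``r P (1 - P/K)``.

    Accepts scalar, array or autodiff-tensor populations; parameters may be a
    :class:`LogisticParams` or any mapping with keys ``r`` and ``K`` (values
    may themselves be tensors during training).
    """
    if _is_numeric(P) and not np.all(np.isfinite(P)):
        raise ValueError("population P must be finite")
    if isinstance(params, LogisticParams):
        r, K = params.r, params.K
    else:
        r, K = params["r"], params["K"]
    return r * P * (1.0 - P / K)


def logistic_analytic(t, params: LogisticParams | Mapping[str, float]):
    """Closed-form logistic solution ``K / (1 + (K/P0 - 1) e^{-rt})``."""
    if isinstance(params, LogisticParams):
        r, K, P0 = params.r, params.K, params.P0
    else:
        r, K, P0 = params["r"], params["K"], params["P0"]
    if P0 == 0:
        raise ZeroDivisionError("P0 must be nonzero for the closed-form solution")
    t = np.asarray(t, dtype=float)
    value = K / (1.0 + (K / P0 - 1.0) * np.exp(-r * t))
    return float(value) if value.ndim == 0 else value


def gene_rhs(state: Sequence[Any], params: GeneBindingParams | Mapping[str, Any]):
    """Mass-action binding kinetics for (prom, tf, promtf).

    Binding consumes free promoter and free transcription factor at rate
    ``k_on * prom * tf`` and the complex dissociates at ``k_off * promtf``;
    the promoter and transcription-factor equations are identical and the
    complex equation is their negation.
    """
    if len(state) != 3:
        raise ValueError(f"gene system state must have 3 components, got {len(state)}")
    prom, tf, promtf = state
    if isinstance(params, GeneBindingParams):
        k_on, k_off = params.k_on, params.k_off
    else:
        k_on, k_off = params["k_on"], params["k_off"]
    free_rate = k_off * promtf - k_on * (prom * tf)
    return [free_rate, free_rate, 0.0 - free_rate]


def gene_equilibrium(params: GeneBindingParams) -> tuple[float, float, float]:
    """Steady state of the binding system from its conservation laws.

    With totals A = prom + promtf and B = tf + promtf conserved, the
    equilibrium complex concentration c solves the quadratic
    ``k_on (A - c)(B - c) = k_off c``.
    """
    A = params.ic[0] + params.ic[2]
    B = params.ic[1] + params.ic[2]
    Kd = params.k_off / params.k_on if params.k_on > 0 else math.inf
    if math.isinf(Kd):
        return (A, B, 0.0)
    # c^2 - (A + B + Kd) c + A B = 0; the physical root is the smaller one
    half_sum = 0.5 * (A + B + Kd)
    c = half_sum - math.sqrt(half_sum**2 - A * B)
    return (A - c, B - c, c)


# -- system factories ---------------------------------------------------------

def logistic_system() -> ODESystem:
    """Logistic growth as a 1-state :class:`ODESystem` (parameters r, K)."""

    def rhs(state, t, params):
        return [logistic_rhs(state[0], params)]

    def analytic(t, params):
        value = logistic_analytic(t, params)
        return np.atleast_1d(value)[:, None] if np.ndim(value) else np.array([[value]])

    return ODESystem(
        name="logistic",
        state_names=("P",),
        rhs=rhs,
        param_schema=(("r", False), ("K", True)),
        analytic=analytic,
    )


def gene_binding_system() -> ODESystem:
    """Promoter/TF binding as a 3-state :class:`ODESystem` (k_on, k_off)."""

    def rhs(state, t, params):
        return gene_rhs(state, params)

    return ODESystem(
        name="gene",
        state_names=("prom", "tf", "promtf"),
        rhs=rhs,
        param_schema=(("k_on", False), ("k_off", False)),
    )


# -- numerical oracle ---------------------------------------------------------

def integrate(
    system: ODESystem,
    params: Mapping[str, float] | LogisticParams | GeneBindingParams,
    ic: Sequence[float],
    t_grid: np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> Trajectory:
    """Solve the initial-value problem on `t_grid` with Dormand–Prince RK5(4).

    The first trajectory row equals `ic` exactly.  Raises ``RuntimeError``
    with the solver's diagnostics if the tolerances cannot be met.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    ic = np.asarray(ic, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if ic.shape != (system.dim,):
        raise ValueError(f"ic must have length {system.dim}, got {ic.shape}")
    if not isinstance(params, Mapping):
        params = params.as_dict()
    system.validate_params(params)

    def fun(t, y):
        return [float(d) for d in system.rhs(list(y), t, params)]

    sol = solve_ivp(
        fun, (t_grid[0], t_grid[-1]), ic, t_eval=t_grid,
        method="RK45", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration of {system.name!r} failed: {sol.message} "
            f"(reached t={sol.t[-1] if sol.t.size else t_grid[0]})")
    states = sol.y.T
    states[0] = ic
    return Trajectory(times=t_grid, states=states, state_names=system.state_names)


def save_params_json(params: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: float(v) for k, v in params.items()}, fh, indent=2)


def load_params_json(path) -> dict[str, float]:
    with open(path) as fh:
        return {str(k): float(v) for k, v in json.load(fh).items()}
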