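"""Synthetic observations, collocation grids, and the two case-study fixtures.

Observations are clean trajectories (closed form when the system has one,
numerical integration otherwise) plus additive i.i.d. Gaussian noise;
collocation points are i.i.d. uniform draws over the time domain.  Both are
reproducible from an integer seed.

The case-study fixtures bundle everything an experiment needs: the system,
its true parameters, the time domain, and the network/training defaults used
throughout the package (layer sizes, collocation counts, noise level,
parameter initial guesses and their conditioning scales).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .ode_models import (
    GeneBindingParams,
    LogisticParams,
    ODESystem,
    gene_binding_system,
    integrate,
    logistic_system,
)

__all__ = [
    "ObservationSet", "CollocationSet", "CaseStudy",
    "sample_collocation", "generate_observations", "make_case_study",
]


@dataclass(frozen=True)
class ObservationSet:
    """Observed state values at sample times, with the noise that made them."""

    times: np.ndarray
    values: np.ndarray
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if times.ndim != 1 or values.shape[0] != times.shape[0]:
            raise ValueError("times and values must align on the first axis")
        if not np.all(np.isfinite(values)):
            raise ValueError("observed values must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path, state_names: tuple[str, ...] = ()) -> None:
        names = state_names or tuple(f"x{i}" for i in range(self.dim))
        frame = pd.DataFrame(self.values, columns=list(names))
        frame.insert(0, "t", self.times)
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, noise_sigma: float = 0.0, seed: int = 0) -> "ObservationSet":
        frame = pd.read_csv(path)
        if frame.columns[0] != "t":
            raise ValueError(f"first column must be 't', got {frame.columns[0]!r}")
        return cls(times=frame["t"].to_numpy(), values=frame.iloc[:, 1:].to_numpy(),
                   noise_sigma=noise_sigma, seed=seed)


@dataclass(frozen=True)
class CollocationSet:
    """Time points where the ODE residual is penalized (no observed data)."""

    times: np.ndarray
    seed: int = 0

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise ValueError("collocation times must be a 1-d vector")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.times.shape[0]


def sample_collocation(n: int, t_min: float, t_max: float, seed: int = 0) -> CollocationSet:
    """Draw `n` i.i.d. uniform collocation points on [t_min, t_max], sorted."""
    if n < 0:
        raise ValueError(f"collocation count must be >= 0, got {n}")
    if not t_max > t_min:
        raise ValueError(f"need t_max > t_min, got [{t_min}, {t_max}]")
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(t_min, t_max, size=n))
    return CollocationSet(times=times, seed=seed)


def generate_observations(
    system: ODESystem,
    params: Mapping[str, float] | LogisticParams | GeneBindingParams,
    times: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
    ic: np.ndarray | None = None,
) -> ObservationSet:
    """Sample the clean solution at `times` and add Gaussian noise.

    The clean solution is the closed form when the system provides one (the
    logistic model), otherwise the numerical oracle; `ic` is then required
    unless the parameter object carries initial conditions.  ``noise_sigma``
    may be a scalar or one value per state; zero yields exact solution values.
    """
    if np.any(np.asarray(noise_sigma) < 0):
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    times = np.asarray(times, dtype=float)
    if isinstance(params, LogisticParams):
        pmap: dict[str, float] = {"r": params.r, "K": params.K, "P0": params.P0}
    elif isinstance(params, GeneBindingParams):
        pmap = params.as_dict()
        if ic is None:
            ic = np.asarray(params.ic)
    else:
        pmap = dict(params)
    if system.analytic is not None:
        clean = np.asarray(system.analytic(times, pmap), dtype=float)
        if clean.ndim == 1:
            clean = clean[:, None]
    else:
        if ic is None:
            raise ValueError("ic is required for systems without a closed form")
        clean = integrate(system, {k: pmap[k] for k in system.param_names()},
                          ic, times).states
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=clean.shape) * np.asarray(noise_sigma, dtype=float)
    return ObservationSet(times=times, values=clean + noise,
                          noise_sigma=float(np.max(noise_sigma)), seed=seed)


@dataclass(frozen=True)
class CaseStudy:
    """A fully configured experiment fixture.

    ``param_init`` are the inverse-problem starting guesses (``None`` means
    "draw uniformly on init_range at fit time"); ``param_scales`` condition
    the optimizer so each trainable parameter is updated on its natural
    magnitude.  ``output_scale`` multiplies the raw network output so the
    tanh trunk works on O(1) values, and ``input_scale`` divides the time
    input likewise.
    """

    name: str
    system: ODESystem
    true_params: dict[str, float]
    ic: tuple[float, ...]
    t0: float
    domain: tuple[float, float]
    hidden_layers: int
    neurons: int
    n_collocation: int
    n_observations: int
    noise_sigma: float
    iterations: int
    input_scale: float
    output_scale: float
    param_init: dict[str, float | None] = field(default_factory=dict)
    param_scales: dict[str, float] = field(default_factory=dict)
    init_range: tuple[float, float] = (0.0, 0.1)

    def observation_times(self, n: int | None = None) -> np.ndarray:
        return np.linspace(self.domain[0], self.domain[1],
                           n if n is not None else self.n_observations)

    def observations(self, n: int | None = None, noise_sigma: float | None = None,
                     seed: int = 0) -> ObservationSet:
        sigma = self.noise_sigma if noise_sigma is None else noise_sigma
        return generate_observations(
            self.system, self.true_params, self.observation_times(n),
            noise_sigma=sigma, seed=seed, ic=np.asarray(self.ic))

    def collocation(self, n: int | None = None, seed: int = 0) -> CollocationSet:
        return sample_collocation(n if n is not None else self.n_collocation,
                                  self.domain[0], self.domain[1], seed=seed)

    def reference(self, times: np.ndarray) -> np.ndarray:
        """Clean solution on `times` (closed form or integrated)."""
        return generate_observations(self.system, self.true_params,
                                     np.asarray(times, dtype=float),
                                     noise_sigma=0.0, ic=np.asarray(self.ic)).values

    def with_overrides(self, **kwargs) -> "CaseStudy":
        return replace(self, **kwargs)


def make_case_study(name: str) -> CaseStudy:
    """Return a ready-to-run fixture: ``"logistic"`` or ``"gene"``.

    logistic: true r=0.5, K=100, P0=1 on t in [0, 100]; 3x50 tanh network,
    500 collocation points, observation noise sigma=1 (1% of K).
    gene: true k_on=1/60, k_off=0.5/60, initial concentrations (17, 25, 0)
    on t in [0, 100]; 4x50 tanh network, 350 collocation points, 300
    noiseless observations.
    """
    if name == "logistic":
        truth = LogisticParams(r=0.5, K=100.0, P0=1.0)
        return CaseStudy(
            name="logistic",
            system=logistic_system(),
            true_params={"r": truth.r, "K": truth.K, "P0": truth.P0},
            ic=(truth.P0,),
            t0=0.0,
            domain=(0.0, 100.0),
            hidden_layers=3,
            neurons=50,
            n_collocation=500,
            n_observations=50,
            noise_sigma=1.0,
            iterations=200_000,
            input_scale=100.0,
            output_scale=100.0,
            param_init={"r": 1.0, "K": 50.0},
            param_scales={"r": 1.0, "K": 100.0},
        )
    if name == "gene":
        truth = GeneBindingParams(k_on=1.0 / 60.0, k_off=0.5 / 60.0)
        return CaseStudy(
            name="gene",
            system=gene_binding_system(),
            true_params=truth.as_dict(),
            ic=truth.ic,
            t0=0.0,
            domain=(0.0, 100.0),
            hidden_layers=4,
            neurons=50,
            n_collocation=350,
            n_observations=300,
            noise_sigma=0.0,
            iterations=10_000,
            input_scale=100.0,
            output_scale=25.0,
            param_init={"k_on": None, "k_off": None},
            param_scales={"k_on": 1.0 / 60.0, "k_off": 1.0 / 60.0},
            init_range=(0.0, 0.1),
        )
    raise ValueError(f"unknown case study {name!r}; choose from 'logistic', 'gene'")
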