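# Methods

## Model

`odepinn` approximates the solution of an autonomous first-order ODE system

    dx/dt = f(x, t; θ),   x(t₀) = x₀,   x ∈ ℝᵈ

with a fully connected tanh network `u(t; w)` mapping scalar time to the d
state variables.  Training minimizes the unweighted sum of three mean
squared terms:

* **data loss** — `mean((u(tᵢ) − yᵢ)²)` over the observations (tᵢ, yᵢ);
* **initial-condition loss** — `mean((u(t₀) − x₀)²)`;
* **physics loss** — `mean((du/dt(tⱼ) − f(u(tⱼ), tⱼ; θ))²)` over the
  collocation points tⱼ, averaged over points and state components.

`du/dt` is the network's exact derivative, obtained by propagating a
forward-mode tangent through every layer (for a tanh layer `a = tanh(Wx+b)`
the tangent is `(1 − a²) ∘ (W ẋ)`).  The tangent pass is built from the same
differentiable operations as the forward pass, so reverse-mode
differentiation through it yields the gradient of the physics loss with
respect to the weights *and* the ODE parameters θ.  With θ frozen this
solves the forward problem (a smooth surrogate of the trajectory); with θ
flagged trainable it solves the inverse problem, estimating the parameters
jointly with the fit.

All three components are weighted equally by default.  Equal weighting
keeps the objective free of extra hyperparameters; the weights are exposed
(`loss_weights`) for problems where one term dominates.

## Automatic differentiation

The package carries its own reverse-mode engine (`odepinn.autodiff`): a
tape of numpy arrays with broadcasting-aware backward closures, plus fused
kernels (`linear`, `dtanh_mul`, `mse`) that keep the tape short on the
training path.  Gradients of constants are never computed.  The engine is
validated two ways in the test suite: every op against central finite
differences (`grad_check`), and the assembled network derivative against a
4th-order finite-difference stencil of the prediction.

## Case studies

Two systems from population biology and gene regulation are built in.

**Logistic growth** — `dP/dt = r P (1 − P/K)` with closed form
`P(t) = K / (1 + (K/P₀ − 1) e^{−rt})`.  Study conditions: r = 0.5 (1/time),
K = 100 (population units), P₀ = 1, domain t ∈ [0, 100]; network 3×50 tanh,
500 collocation points.  Inverse-problem starting guesses r₀ = 1, K₀ = 50.

**Promoter/TF binding** — mass-action kinetics for (prom, tf, promtf):
binding at `k_on·prom·tf`, dissociation at `k_off·promtf`.  The promoter
and transcription-factor equations are identical and the complex equation
their negation, so `prom + promtf` and `tf + promtf` are conserved (here
17 and 25 concentration units).  Study conditions: k_on = 1/60,
k_off = 0.5/60, initial state (17, 25, 0), domain [0, 100], 300 observation
points; network 4×50 tanh, 350 collocation points; rate guesses drawn
uniformly on [0, 0.1].  The equilibrium follows from the conservation laws
as the smaller root of `c² − (A + B + K_d)c + AB = 0` with A = 17, B = 25,
K_d = k_off/k_on — the oracle used to check long-horizon integration.

## Conditioning choices

Three rescalings make Adam at learning rate 1e-3 effective on these
problems; all are exposed as parameters and logged with each run.

* **Input scale** — time is divided by the domain width (100) before the
  first layer, so the tanh trunk sees O(1) inputs instead of saturating.
* **Output scale** — raw outputs are multiplied by the expected state
  magnitude (100 for the logistic population, 25 for concentrations).
  Without it the last layer's weights would have to grow to O(100), which
  gradient descent does slowly.  An optional softplus transform is
  available when states must stay nonnegative; the case studies use the
  affine scale, which worked without the constraint.
* **Parameter scale** — each trainable ODE parameter is optimized as
  `value/scale` with scale near its expected magnitude (K: 100, binding
  rates: 1/60).  Adam's effective step is ~lr per iteration regardless of
  gradient magnitude, so without this K could move at most ~0.001 per step
  and could not traverse 50 → 100 inside the iteration budget, while the
  rates (~0.02) would be updated violently.  Positivity of parameters is a
  validation-time check, not a transform: the optimizer sees an
  unconstrained variable.

## Training

Full-batch Adam (β = 0.9/0.999, ε = 1e-8, lr 1e-3): every step evaluates
all observations and collocation points.  At a few hundred points,
mini-batching would only add gradient variance.  The loop is deterministic
given the seed — weight initialization (Glorot uniform), collocation
draws, observation noise and random parameter guesses all derive from it —
and two identical runs produce bit-identical histories.

The best-so-far weights (lowest total loss) are restored when the loop
ends, so a late divergence cannot degrade the returned model.  There is no
automated early stopping: `has_converged` (relative change of the smoothed
logged total over a trailing window, strict inequality) is a diagnostic,
not a control.  A non-finite loss aborts with the iteration and offending
component named.

Default iteration counts follow the case studies: 200,000 for the logistic
fixture, 10,000 for the binding fixture.  The experiment runners and tests
use scaled-down counts — 50,000 for logistic inverse runs, 20,000 per model
in the comparison, 10,000 for forward solves — which the convergence checks
below show to be sufficient for these problems.

## Synthetic data

Observations are clean solutions (closed form for the logistic system,
Dormand–Prince RK5(4) integration otherwise) plus additive i.i.d. Gaussian
noise, equally spaced over the domain unless times are supplied.  The
logistic comparison uses σ = 1.0 population units (1% of K); the case-study
inverse and forward runs use noiseless samples, mirroring data generated
directly from the true model.  Collocation points are i.i.d. uniform draws
over the domain, sorted for reproducible logging.

What the generator does *not* emulate: measurement noise that grows with
signal, irregular or censored sampling, model misspecification (the
generating ODE is exactly the fitted ODE), and unobserved state components.
Passing tests therefore demonstrate correct mechanics and recoverability
under ideal identifiability conditions, not robustness on real assay data.

## Numerical choices

* Integrator: adaptive Dormand–Prince RK5(4) (`scipy.solve_ivp`, RK45) with
  rtol 1e-9 / atol 1e-11.  These tolerances keep the accumulated error on
  the logistic benchmark near 1e-7 over the full domain, an order below the
  1e-6 agreement the oracle tests assert; the looser 1e-8/1e-10 pair
  measurably misses that bar (2e-6).  The systems are non-stiff at the
  study parameters.
* The physics residual for multi-state systems is the mean over states of
  per-state mean squared residuals (equivalent to the grand mean over the
  points × states matrix).
* Ties in the best-so-far tracking resolve to the earliest iteration
  (strict improvement required).
* `has_converged` compares first- and second-half means of the trailing
  window; relative change exactly equal to the tolerance counts as not
  converged.
* Checkpoints are JSON (architecture header + weights + ODE parameters);
  restoring into a mismatched architecture fails naming the differing
  field.

## Known limitations

* A forward solve from the initial condition and physics alone collapses
  to the trivial flat solution on this long domain (the residual has an
  attracting minimum at P ≡ 0); `run_forward` therefore includes noiseless
  reference samples by default.  Curriculum/domain-splitting schemes that
  fix this for pure IC+physics training are out of scope.
* Single optimizer (Adam).  A quasi-Newton refinement phase would sharpen
  final estimates but is not needed at the tested tolerances.
* No identifiability analysis: with sparse, noisy or partially observed
  data, different (r, K) or (k_on, k_off) pairs can fit comparably well,
  and estimates should be read with that caveat.
* Stiff systems, PDEs, delay and higher-order equations are out of scope
  (reduce higher-order systems to first order before use).
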