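# Methods

This note documents the models, protocols and numerical choices behind
`pinneco`, and what the synthetic testbeds can and cannot show.

## Process models

### Predator–prey system

The data-generating model is a Lotka–Volterra system with a sigmoidal
(type III) functional response,

```
dx/dt = r x − b x² y / (1 + s x²)
dy/dt = b x² y / (1 + s x²) − m y
```

with prey density x, predator density y, prey growth rate r (1/time),
feeding rate b, predator mortality m and prey searching time s. Default
study constants: r = 0.1, b = 0.02, m = 0.04, s = 0.025, initial densities
x₀ = y₀ = 10, horizon 130 time units, output grid 0.5. The mis-specified
process model replaces the sigmoidal term with a linear (type I) feeding
term b·x·y and assumes initial densities (12, 10); the initial state is part
of the model configuration and is never estimated. The type I system is
conservative — H(x, y) = b·x + b·y − m·ln x − r·ln y is constant along
interior orbits — which matters scientifically: a type I model started away
from its equilibrium cycles forever and *cannot* reproduce the damped
plateau the type III system settles into. The tests use H-drift as an
integrator diagnostic.

Integration is classical fixed-step RK4, internal step 0.05 by default with
outputs subsampled to the requested grid. During gradient calibration the
internal step equals the output grid (0.5); for these rates the RK4 error at
step 0.5 is ~1e-7 density units, far below the observation scale, and final
evaluations are re-run at 0.05. Prey observations are drawn uniformly
without replacement from the output grid; Gaussian observation noise may
push readings negative and they are kept as-is (downstream consumers accept
them).

### Light-use-efficiency flux model

A deliberately small, fully documented ecosystem model with three coupled
subsystems — productivity, transpiration, soil water — structured like the
semi-empirical light-use-efficiency models used for forest carbon fluxes,
but *not* a port of any published parameterisation (its role here is to be a
controllable process model, and, structurally perturbed, the data-generating
truth). Daily gross primary productivity is

```
P_k = β · φ_k · faPPFD_k · f_T,k · f_D,k · f_W,P,k
```

with the modifiers

* `f_T = 1 / (1 + exp(−k_temp (T̄_k − t_opt)))` — logistic in a seasonally
  acclimated temperature state T̄, an exponential moving average of air
  temperature with window `tau_temp` (days); this delays spring up-regulation
  realistically instead of reacting to single warm days;
* `f_D = exp(−kappa_vpd · D)` — exponential decline in vapour pressure
  deficit (kPa);
* `f_W,P` — piecewise-linear ramp in relative soil water θ_soil/capacity
  between fractions `wp_lo` and `wp_hi`.

Transpiration is tied to productivity, `E = alpha_et · P · D^0.6 · f_W,E`,
with `f_W,E` a ramp from 0 to `we_hi` (the exponent 0.6 is fixed, not
calibrated). The water balance keeps soil, surface and snow pools:
precipitation falls as snow at T ≤ 0 °C and rain otherwise; snow melts at a
degree-day rate `melt_rate`; rain and melt pass through the surface pool and
infiltrate the same day (the surface pool is therefore always empty at the
daily reporting step); E is withdrawn from soil, capped by availability;
soil above `capacity` runs off the same day. Modifiers use the *previous*
day's soil pool, so the daily balance θ_k − θ_{k−1} = R_k − E_k − runoff_k
closes exactly (tested to 1e-9 mm). CO₂ is accepted as a covariate but
unused by the default modifiers; day of year never enters the process model
directly.

Eleven named parameters with uniform prior bounds are declared in
`flux.PARAM_TABLE` (value, lower, upper); defaults double as the truth
values of the synthetic generator. Initial pools are soil = 0.7·capacity and
zero elsewhere unless configured; on the autodiff path the initial soil pool
is a differentiable function of capacity.

## Autodiff substrate

All differentiable computation runs on a small reverse-mode tape over numpy
float64 arrays (`pinneco.autodiff`), with exactly the operations the package
needs (arithmetic, exp/log/sqrt, tanh/sigmoid/relu, min/max/clip/where,
batched matmul, indexing, stack/concatenate, reductions). Both process
models are written generically, so the same code runs on plain numbers
(dispatched to numba-compiled kernels, batched over parameter vectors) or on
tape Tensors; unit tests pin the two paths to each other at 1e-10 relative.
Hot training loops use analytic derivatives instead of the tape where the
tape would dominate runtime: predator–prey gradient calibration integrates
forward sensitivities (the 2×4 Jacobian system) alongside the state with the
same RK4 scheme, and a test verifies that this gradient equals the tape
gradient to 1e-9 relative.

Kinks (min/max/clip in the water balance, ReLU) get the standard subgradient
convention: ties route the gradient to the first argument. Gradient-check
tests use inputs nudged off the kinks; finite differences at a kink are not
expected to match and the test fixtures avoid them.

## Model variants

Feature handling for the flux networks: covariates are z-scored with
training-set statistics; day of year is encoded as a (sin, cos) pair by
default (flag-switchable to the raw integer) to remove the artificial
discontinuity at year boundaries; targets (or residuals, for parallel
physics) are z-scored for optimisation and rescaled for prediction. The last
layer is always linear and losses are MSE — regression under a normality
assumption. Defaults: two hidden layers, width 32, ReLU, full-batch Adam.

* **bias correction** consumes the calibrated PM's (P, E, θ) as features.
* **parallel physics** learns the residual y − ŷ_PHY from covariates;
  prediction adds the PM back.
* **physics regularisation** shares the parallel-physics structure but only
  penalises disagreement with the PM in the loss (λ ∈ [0, 1]); the PM is not
  added at prediction time.
* **domain adaptation** is a protocol, not an architecture: (1) draw
  parameter vectors from the prior by Latin hypercube, generate covariate
  series from a harmonic (3 annual Fourier terms + residual bootstrap)
  surrogate fitted to the observed covariates, simulate targets with the PM,
  pre-train the naive architecture on the pooled simulations; (2) fine-tune
  on observations with the phase-1 feature scaling. Phase-1 data carries a
  taint flag (`has_observed_targets=False`) and the trainer refuses
  anything else, so simulator pretraining provably never reads observed
  targets. The surrogate is evaluated on a contiguous daily template even
  when observations are weekly, because the PM recursion needs daily steps.
* **physics embedding**: a parameter network maps standardized covariates to
  per-day raw outputs; these are averaged over the series (evaluation batch
  = full series, so the PM receives one parameter vector, like a stand-alone
  calibration would) and squashed into the prior bounds with a scaled
  sigmoid — averaging before squashing keeps the mean meaningful and makes
  out-of-bounds parameters impossible by construction. The PM runs on the
  tape; its (P, E, θ) outputs are standardized *on the tape* (so gradients
  see the normalisation) and feed the bias-correction network. λ defaults
  to 1.

## Calibration

* **MCMC**: adaptive random-walk Metropolis within uniform prior bounds.
  Per-parameter proposal scale is c·(2.4/√d)·width with the global factor c
  adapted every 50 iterations during burn-in towards an acceptance rate of
  0.234; proposals outside the bounds are rejected; a zero-acceptance window
  triggers a step-size warning. The likelihood is Gaussian with the model
  prediction as mean and a fixed standard deviation of 1 (configurable).
  The first half of each chain is discarded for summaries; the MAP is the
  best post-burn-in draw. Correctness checks: a flat likelihood reproduces
  the uniform prior (KS test per parameter), a 1-D quadratic log-likelihood
  reproduces the analytic posterior variance within 10%, and dense
  noise-free predator–prey data recover (r, b, m) within 5%.
* **Gradient calibration** (predator–prey): Adam on the MSE between
  predicted and observed prey, gradients from forward sensitivities,
  parameters clipped to bounds after every step. All folds, seeds and
  scenarios calibrate as one batched kernel call per epoch.

For the flux experiments the PM used inside the hybrids is the MAP of the
experiment's own calibration run (per training split), not a default
parameterisation.

## Protocols

Blocked cross-validation holds out whole years, whole sites, or site-years;
the test block is excluded from every fold and `check_cv_plan` asserts the
partition. Sparse scenarios keep every 7th row per site starting at the
first (a 365-day year yields 53 rows: days 1, 8, …, 365). The random search
draws architectures and optimisation parameters jointly and scores each
candidate by mean validation MSE across folds; the full log is returned.
There is no early stopping anywhere — epoch budgets are fixed and loss
curves are persisted for inspection.

## Synthetic multi-site data

The generator emulates a five-site network spanning boreal to mediterranean
climates and evergreen/deciduous canopies, observed over four to seven years
in the full layout (`study_sites()`); the compact default uses three years
per site. Temperature is a seasonal sinusoid plus AR(1) noise; radiation a
clear-sky sinusoid damped by cloudiness coupled to rain occurrence; VPD
grows exponentially with temperature and drops on wet days; precipitation is
a seasonal occurrence/intensity process (dry-summer regime for the
mediterranean site); faPPFD follows a phenology curve held constant within
8-day blocks, mimicking the resolution of the satellite product such data
come from; CO₂ is constant per site.

The observed target is the flux model run with site-specific parameter
offsets **plus planted structural mismatch** applied to productivity inside
the recursion (so the water cycle feels it): a radiation-saturation factor
1/(1 + φ/φ_sat) at all sites, and a site-varying rain sensitivity
exp(−c_R·R) (zero at the boreal target site, so the saturation signal is
clean there). Observation noise is Gaussian with sd = 0.05 + 0.08·√P — a
floor plus a heteroscedastic component. The noise-free truth is stored
alongside for oracle tests.

What the testbed does not emulate: eddy-covariance gap-filling and u*
filtering artefacts, energy-balance closure issues, satellite-product noise
in faPPFD, disturbance and phenology trends, and any quantitative match to
real sites. Passing the transfer experiments therefore shows the framework's
machinery is sound and that hybrids can exploit a *known* structural gap; it
does not certify performance on real flux towers.

## Evaluation and inference

Accuracy is MAE; pooled MAE equals the fold-size-weighted mean of per-fold
MAEs by construction. "Quantile association" is reported as the pair
(decile Q–Q table, Spearman rank correlation): the table separates level
bias from rank skill, and the rank component is invariant under monotone
transforms. ICE varies one covariate over 25 equally spaced points spanning
its observed range extended by 10% (clipped to physical bounds), predicting
daily P over the first 14 days of March, June, September and December and
averaging each window. Per-day replacement (default) and whole-window
replacement are both available; they coincide for pointwise models and
differ only through carried-over water state for the PM — per-day
replacement makes the PM's radiation curve an exact ray through the origin,
which the tests exploit. Model comparison uses a normalised departure: both
models' curves are centred per window and the mean absolute difference is
averaged over grid and seasons.

## Predator–prey experiment protocol

Networks condition the prey density at a time on a previous prey value and
the two time stamps (two hidden layers of width 50, tanh, raw inputs and
targets, full batch, Adam at 1e-4). Two readings of "previous prey value"
are implemented for training (`paired`: the previous observation;
`chained`: the model's own previous prediction, backpropagated through the
chain) and for full-grid evaluation (`anchored`: the latest training
observation; `recursive`: the model's own prediction at the previous grid
point, rolled from the earliest observation). Defaults are paired training
and recursive evaluation. The process model is gradient-calibrated per
leave-one-out fold from the generator's parameter values; the default
schedule is the scaled one (6,000 PM steps, 20,000 network steps at the
published learning rates; the full 60k/200k schedule is an argument).

A finding worth recording: under these conditions the mis-specified type I
process model is *not* the best model in the structural-error scenarios.
Its observation-MSE landscape has a local basin at full-series MAE ≈ 1.0
(both Adam and plain gradient descent land there from the default
parameter values; even the global optimum of the observation fit, located
by differential evolution, has full-series MAE 0.47 — the conservative
type I structure cannot damp to the truth's plateau), while a competently
trained MLP conditioned on a previous prey value interpolates the mostly
flat trajectory at MAE 0.2–0.9 under every protocol combination we tried.
The classical qualitative ordering PM ≤ hybrid ≤ MLP therefore reproduces
fully in the correct-structure scenario and as PM ≤ parallel-physics in the
structural-error scenarios, but the naive MLP is stronger than the ordering
presumes; the acceptance suite asserts the full ordering and reports this
honestly.

## Problem sizes and determinism

Default experiment sizes are chosen to make a complete study (tests plus
acceptance script) run in tens of minutes on one CPU core: five seeds ×
three scenarios × nine folds for the predator–prey study (all trained as
one batched ensemble), three seeds for the transfer experiment (five sites ×
three years, sparse weekly training, 2,500 MCMC iterations × 2 chains,
1,500 network epochs), four seeds for the ICE study. Every stochastic
component takes an explicit seed or Generator; equal seeds give bit-identical
results (numpy/numba arithmetic is deterministic; no threading is used).

## Known limitations

* The flux mini-model is a structural stand-in: it preserves the
  light-use-efficiency core and the P–E–θ coupling of production models but
  none of their calibrated realism (no CO₂ response by default, fixed E
  exponent, single soil bucket).
* The Metropolis sampler is adequate for the 3–11 parameter posteriors here
  but makes no claim to efficiency in higher dimensions; chains are
  independent (no ensemble moves).
* The embedding trains on full-series batches only, and its runtime grows
  linearly with series length because the PM recursion runs on the tape.
* ICE curves for the PM inherit its daily time-stepping: whole-window
  replacement perturbs the water state and is therefore not a pure partial
  dependence; use per-day mode for structural checks.
* Gradients at water-balance branch points are subgradients; optimisers
  cross them without issue in practice, but second-order methods would not.
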