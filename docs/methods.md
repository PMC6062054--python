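# Methods

## Model and assumptions

A static-chamber closure is described by the Hutchinson–Mosier
regression (HMR) curve

    C(t) = φ + f₀ · exp(−κt) / (−κh),

a pseudo-steady-state solution of Fick's first law with a constant
source concentration φ at depth.  Its assumptions — one-dimensional
diffusion, vertically uniform soil, all nonlinearity absorbed into one
shape parameter κ — are crude, but κ soaks up leakage, lateral
transport and gradient feedback alike, which is exactly why the model
is useful as a *family of curvatures* rather than as a process model.
κ → 0 recovers the straight line; uptake fluxes (f₀ < 0) are fully
supported.

Unit conventions: all internal computation is in seconds, ppb and
nmol.  A mole fraction x (ppb) converts to an amount concentration of
x·p/(RT) nmol m⁻³ by the ideal gas law; the default conditions are
T = 293.15 K and p = 101325 Pa (both configurable on `ChamberSystem` —
field campaigns that log air temperature and pressure should set
them).  A concentration slope b (ppb s⁻¹) maps to a flux
b·h·p/(RT) nmol s⁻¹ m⁻².  The effective chamber height h defaults to
volume/area, with an explicit override field for chambers whose
nominal height differs from V/A (e.g. collar insertion).  Model time
is measured from the first sample of each closure.

## Base estimators

**Linear (LR).**  Closed-form ordinary least squares; the slope
standard error propagates to the flux.  AIC is computed under a
Gaussian error model as n·log(SSE/n) + 2k with k = 3 (slope,
intercept, error variance); an SSE floor of (10⁻⁶ ppb)²·n keeps the
logarithm finite on noiseless synthetic data.

**Robust linear (RLM).**  Iteratively reweighted least squares with
the Huber ψ at c = 1.345 and MAD-based residual scale, capped at 50
iterations (plain OLS is returned, flagged, if IRLS fails to settle).
With the minimum of four samples the first and last points always keep
full weight: they anchor the only leverage the design has, and
down-weighting them would let the middle points dominate the slope.
On data with zero residual spread RLM reduces exactly to OLS.  The
implementation is hand-rolled because the endpoint rule is not
expressible in the standard library implementations; statsmodels' RLM
serves as an independent cross-check in the tests on longer series
where the rule is inactive.

**HMR (profiled partial-linear least squares).**  For fixed κ the
model is linear in (φ, β) with β = f₀/(−κh), so the conditional
optimum and SSE are available in closed form (`hmr_profile_sse`).  The
remaining 1-D problem in κ is solved by variable-projection
Gauss–Newton on u = log κ with step halving — the same iteration
discipline as standard nonlinear-least-squares tooling (relative-offset
convergence tolerance 10⁻⁵, iteration cap 50, smallest step factor
1/1024).  The starting value is data-driven: the ratio of the first to
the last concentration increment gives the classic three-point
estimator κ₀ = log(d_first/d_last)/(t₋₂ − t₀) whenever the increments
indicate decay; otherwise a conventional 1.5 h⁻¹ is used.

The fit *deliberately fails* — returning non-convergence, upon which
every scheme falls back to the linear estimate — when the iteration
hits a flat SSE plateau (exp(−κt) underflown at every t > 0: a
step-shaped, unidentifiable fit), a singular gradient, or exhausts its
step-halving budget, or when the final κ lies at the search bounds
[10⁻⁷, 1] s⁻¹ (within a 10⁻³ relative margin) or the SSE does not beat
the straight line's.  This failure behaviour is a feature, not a
limitation: a local optimum that cannot be reached robustly from a
sensible start is not determined by the data, and accepting it would
only amplify noise.  A global scan over κ was evaluated and rejected
during development — it dutifully finds shallow noise-induced SSE
minima on zero-flux data and roughly doubles the nonlinear schemes'
detection limits.  Consequence of the local search: the fitted SSE is
the optimum of its basin, not necessarily the global profile minimum;
the tests assert local optimality (SSE below the profile at nearby κ)
and cross-check the full solution against an independent
Levenberg–Marquardt fit on identifiable data.

## Decision schemes

All nonlinear schemes share the fallback: a non-converged HMR fit
yields the linear estimate with reason `hmr_not_converged`.

* `LR`, `RLM` — always the (robust) linear flux.
* `HMR` — the nonlinear flux whenever the fit converges.
* `AIC` — lower AIC wins (k = 3 linear vs k = 4 HMR; at n = 4 this
  reduces to choosing HMR when SSE_hmr < e^(−1/2)·SSE_lin).  The
  small-sample correction AICc is undefined at n = 4 for these k and
  is not used.
* `GFACTOR` — HMR unless |f_hmr| > g_max·|f_lin| (default 4; absolute
  values, so amplified uptake is capped symmetrically).
* `FIXEDKAPPA` — HMR unless κ ≥ threshold; the threshold is specified
  in h⁻¹ (default 20) as is conventional, converted internally.
* `KAPPAMAX` — HMR unless κ exceeds κ_max = |f_lin|/(f_det·t_meas).
  |f_lin| extends the rule symmetrically to uptake fluxes.  t_meas is
  the last-minus-first sample time of each closure by default, with a
  config override since the right time factor is an open methodological
  question.  A fitted κ exactly at the bound is accepted (the threshold
  is an upper bound).

Batch summaries report the hmr-selected count, arithmetic mean flux,
the deviation ratio against LR on the same closures, and a geometric
mean computed on a positive-shift convention (shift by |min| + 10⁻³
when non-positive fluxes are present) — fluxes can be zero or
negative, so the plain geometric mean is undefined and the shifted
variant is reported alongside the arithmetic mean.

## Minimal detectable flux

`simulate_f_det` generates n_sim (default 1000) zero-flux closures —
the ambient baseline plus i.i.d. Gaussian noise of sd_gc at the
sampling times — estimates each flux with the chosen scheme, and takes
an empirical quantile (linear interpolation; default 0.975) of the
signed estimates.  For LR this equals, in expectation, the closed form
z(q)·sd_gc/√Σ(t−t̄)²·h·(p/RT) (`analytic_f_det_linear`), which the
simulation must match within empirical-quantile error — the oracle
test.  The quantile of absolute estimates is available as an option.

Two estimate populations are exposed for HMR-based limits: the scheme
as applied (linear fallback included, the default) and the converged
nonlinear fits alone.  The converged-only population is small (~17% of
zero-flux series) so its quantiles carry substantial Monte-Carlo
spread at n_sim = 1000.

The kappa.max scheme consumes f_det, so its own detection limit is
simulated only when an f_det (normally from a prior HMR-based run) is
supplied; without one the request is refused as circular.

## Simulation framework

`run_grid` evaluates schemes over an (f₀ × κ) grid.  Defaults: 25 flux
levels — zero plus 24 log-spaced values in 0.01–5 nmol s⁻¹ m⁻² (the
grid must include the null flux, which a pure log grid cannot) — 25
log-spaced κ in 10⁻⁶–10⁻² s⁻¹, 50 replicates per cell, 4 samples at
0/12/24/36 min.  Within a cell all schemes judge the same simulated
series and the same base fits (paired design); per-cell RNG substreams
are derived counter-style from the master seed, so results are
reproducible and independent of iteration order.  Cell metrics: median
estimate (the heatmap quantity), IQ90 = q95 − q5, bias = mean − true
f₀ (the mean-based convention; the median is stored separately),
population variance, and MSE ≡ bias² + variance, which holds exactly
by construction.  The fraction of replicates in which the scheme chose
the nonlinear fit is stored per cell; `hmr_transition_kappa` condenses
it into the curvature level at which a scheme stops trusting HMR
(largest κ with acceptance ≥ 50%, geometric-mean across flux columns).

`sweep_parameter` varies sd_gc or the total deployment time (sampling
times rescaled to 0, t/3, 2t/3, t, mirroring the case-study design);
for kappa.max runs, f_det is re-simulated per swept value because it
depends on both precision and timing.

`project_dataset` bins a set of flux decisions onto the grid by
estimated flux and fitted κ.  Bin edges are geometric midpoints on the
log axes (arithmetic next to the zero-flux level); fluxes beyond the
grid maximum land in the top flux bin, and closures without a fitted κ
land in the largest-κ row — they were calculated linearly, whose
uncertainty that row's linear metrics represent.  Projected mean
IQ90/bias/MSE weight the cell metrics by raw histogram counts.

## Synthetic campaign generator

`generate_fixture_dataset` emulates a multi-season four-point chamber
campaign: true fluxes from a log-normal with median 0.15 nmol s⁻¹ m⁻²
and log-sd 1.2 (capped at 5 — a realistic right-skewed shape in which
a few emission events dominate the budget), 5% exact zero fluxes, κ
log-uniform over 10⁻⁶–10⁻² s⁻¹, independent draws.  What it does *not*
emulate: temporal autocorrelation of fluxes, any flux–κ dependence
(wet soils plausibly couple the two), non-Gaussian or
concentration-dependent instrument error, and chamber-deployment
artifacts beyond what κ absorbs.  Tests passing on these fixtures
therefore validate the estimation and decision machinery under the
model's own assumptions; they do not certify performance on real
campaigns whose error structure differs.

## Problem sizes and numerical choices

The test suite runs the campaign comparison on 5470 synthetic closures
with a 13 × 13 grid at 20 replicates per cell, and sensitivity sweeps
on 9 × 13 grids — sizes chosen so the whole suite completes in about a
minute while leaving the orderings it asserts far from their noise
floor; the library defaults (25 × 25 × 50) remain the recommended
production setting.  Detection limits use the conventional 1000
zero-flux simulations.  Degenerate inputs are refused loudly
(non-monotone times, fewer than 4 samples, zero noise in a detection
simulation); exp underflow in the profile is detected and treated as
the unidentifiable two-level fit.  Empirical quantiles use linear
interpolation throughout.

## Known limitations

* The AIC scheme's simulated detection limit (~0.039–0.041
  nmol s⁻¹ m⁻² for the default system) sits close to the g-factor
  scheme's; selection rules that prune the accepted-nonlinear tail
  more aggressively would lower it.
* The Gauss–Newton failure modes, while deliberate, make the accepted
  set depend on the starting-value heuristic; series with non-monotone
  early increments but genuine curvature may fall back to linear more
  often than a multi-start search would.
* Water-vapour/pressure corrections, multi-gas closures and
  gap-filling of campaign time series are out of scope.
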