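# Methods

## The estimation problem

`reslife` estimates the survival function S_U of a failure-time T when the
only usable observations are *residual lifetimes*: durations from a
screening ("prevalence") day to failure or censoring, collected from
subjects who already had the condition at screening.  Onset dates in such
prevalent cohorts are often recalled years after the fact, so the package
deliberately discards them and works with the error-free residual
durations V_i and their event indicators δ_i alone.

The price of discarding onsets is an assumption: onsets must arise from a
stationary Poisson process.  Under stationarity the residual lifetime is
the forward recurrence time of a stationary renewal process with
inter-arrival survival S_U, so its density is

    f_res(t) = S_U(t) / μ,        μ = E(T) = 1 / f_res(0),

which is non-increasing in t, and

    S_U(t) = f_res(t) / f_res(0).                                   (plug-in)

Everything in the package flows from these two identities.  Without
stationarity, residual lifetimes alone carry no information about S_U and
no estimator in this package is valid.

## Parametric estimators (`reslife.families`)

Five families are supported for T — exponential, Weibull, log-logistic,
log-normal, gamma — each inducing a residual law with density S_U(·;θ)/μ(θ)
and survival

    S_res(t; θ) = ∫_t^∞ S_U(x; θ) dx / μ(θ).

The censored-data log-likelihood is Σ_i δ_i log f_res(V_i;θ) +
(1−δ_i) log S_res(V_i;θ).  All S_res expressions are closed forms built
from partial expectations (regularized incomplete gamma/beta functions and
the normal CDF), so no quadrature enters the optimizer.  One numerical
subtlety matters: for large Weibull shapes, (t/λ)^k underflows to zero and
a naive incomplete-gamma evaluation returns S_res ≡ 1, silently rewarding
degenerate near-point-mass fits under administrative censoring; in that
regime the small-argument expansion S_res ≈ 1 − (t/λ)/Γ(1+1/k) is used.

Fitting maximizes the log-likelihood with L-BFGS-B on log-transformed
positive parameters (meanlog kept raw), restarting from three
deterministic moment-style initializations; the best local maximizer wins.
The log-logistic shape is bounded below by 1 + 1e−6 because shapes ≤ 1
have infinite mean and hence no residual law.  All-censored data are
refused; non-convergence of every start is reported via `converged=False`.

Mean parameters: all times are in the user's units (the simulation uses
abstract units on a 0–50 calendar window).  No internal rescaling occurs.

## Nonparametric estimator (`reslife.npmle`)

Since f_res is non-increasing, its NPMLE for uncensored data is the
Grenander estimator: the left derivative of the least concave majorant of
the empirical CDF, computed here by weighted pool-adjacent-violators on
the ECDF chord slopes.  Right censoring is handled by EM self-consistency:

* Support cells end at {distinct event times} ∪ {largest observation};
  if the largest observation is censored, its mass is absorbed by the
  terminal cell, so the fitted residual CDF reaches 1 at the data frontier.
* E-step: each censored observation redistributes unit mass over cells
  strictly to its right, proportionally to current cell masses (a censored
  observation with no support to its right is assigned to the terminal
  cell and logged).
* M-step: weighted Grenander refit on the completed masses.
* Convergence: sup-norm change of the fitted CDF below 1e−7, at most
  2,000 iterations; the observed-data log-likelihood is non-decreasing
  across iterations and is checked in the tests.  Fully uncensored input
  short-circuits to the plain Grenander estimator.

Predictions beyond the fitted support are exactly 0 on both scales, which
keeps the cross-validated stacking objective well defined.

### Boundary correction

The Grenander value at 0 is famously unstable and inconsistent — it
inflates without bound as n grows — yet the plug-in estimator divides by
exactly that value.  Two corrections are implemented:

* `quantile_chord(q)`: the chord F̂(t_q)/t_q of the fitted CDF at its
  q-th quantile;
* `merge_first_segments`: the chord from the origin to the second knot.

The default resolves to `quantile_chord(q)` with q = min(1/2, n^(−1/3)).
The cube-root window matches the Grenander boundary convergence rate: it
shrinks slowly enough to average away the spike yet fast enough to remain
consistent for f_res(0+), and at moderate n it still tracks a genuinely
steep density near 0.  Both failure modes are real in this package's own
study designs: merging two segments stays inside the spike and
overestimates f_res(0) by ~75% regardless of n for Weibull-type data,
while a fixed median chord underestimates f_res(0) several-fold when the
density genuinely plunges near 0 (the mixture design below).  The exact
rule used by the original corrected-NPMLE literature is not restated in
the sources available to this package; the adaptive chord is this
package's own documented choice and is configurable.

## Stacking (`reslife.stacking`)

The stacked estimator is a convex combination of m submodel curves,

    Ŝ_res,stack(t) = Σ_k α_k Ŝ_res,k(t),   α_k ∈ [0,1], Σ α_k = 1,

with the same weights reused on the underlying scale (each parametric
submodel contributes S_U(·;θ̂_k); the NPMLE contributes the plug-in curve).
Weights minimize an inverse-probability-of-censoring-weighted Brier score
evaluated at nine equally spaced interior times t_r = r·V_max/10 and
summed over subjects, with held-out predictions from stratified 5-fold
cross-validation (folds stratified by event indicator so every training
set contains events; a submodel that fails on a fold falls back to its
full-data fit, logged).  The IPCW weights are the standard Graf form with
Ĝ the Kaplan–Meier estimator of the censoring survival (computed via
lifelines by swapping the event indicator): subjects failing by t_r weigh
1/Ĝ(V_i−), subjects still at risk weigh 1/Ĝ(t_r), subjects censored by
t_r contribute nothing.  Left limits of Ĝ use the previous step value.

The weight problem is a quadratic program over the probability simplex.
With at most a dozen submodels it is solved exactly by support
enumeration: for every candidate nonzero-support the equality-constrained
least-squares solution is read off the KKT system, infeasible candidates
are discarded, and the feasible candidate with the lowest objective wins.
This is deterministic and free of solver-tolerance artifacts; ties across
supports (the objective is often very flat when submodels nearly agree)
resolve to the first lowest-objective support encountered.

Bootstrap bands resample (V_i, δ_i) pairs with replacement, re-run the
entire pipeline per resample (fits, cross-validation, weight
optimization), and report pointwise percentile bands; resamples without
events are redrawn with bounded retries.

## Synthetic prevalent cohorts (`reslife.simulate`)

The generator reproduces the study conditions of the source simulation:

* Onsets O ~ Uniform(0, 50); prevalence day R = 50.
* Failures T from either Weibull(shape 2, scale 2) or the four-component
  equal-weight mixture of Weibull(4, 2), Log-Logistic(1, 2),
  Log-Normal(−5, 1) and Gamma(25, 1), drawn by a multinomial component
  pick.  The mixture parameters are used verbatim even though the
  log-normal component is nearly a point mass near zero and the
  log-logistic component has infinite mean — sampling requires no finite
  mean, and the resulting kinked survival curve is the point of the
  design.
* Left truncation: (O, T) pairs are rejected until T > 50 − O, giving
  residuals V = T − (50 − O); n = 125 per run by default.
* Administrative censoring: the end-of-study date is the empirical (1−p)
  quantile of the drawn residuals, so exactly ⌈p·n⌉ observations are
  censored, p ∈ {0.1, 0.2, 0.3, 0.4}.
* Random censoring: independent Exp(rate) censoring times with the rate
  calibrated by deterministic root search so the expected censored
  fraction over a 100,000-subject pilot sample from the same generator is
  within 0.01 of the 30% target.

Estimators are scored by the discrete integrated squared survival error

    DISSE = Σ_{j≥2} (t_j − t_{j−1}) (Ŝ(t_j) − S_0(t_j))²

on the uniform mesh 0 = t_1 < … < t_k = 50 with gauge 0.1, against the
generator's true underlying survival (closed form for the Weibull; the
0.25-weighted component survivals for the mixture).  The sum starts at the
second mesh point — the only well-defined reading of a mesh that begins at
its first point — which costs nothing for valid estimators since both
curves equal 1 at t = 0.

The study driver runs the full per-run pipeline (individual fits, CV,
weights, stacked curves), seeds every run from one master generator, logs
and excludes failed runs, and aborts if more than 10% fail.

### What the generator does and does not emulate

It reproduces left truncation, length bias, the stationarity-compatible
uniform onset stream, and both censoring mechanisms.  It does not emulate
onset measurement error (irrelevant here because onsets are discarded),
covariates, calendar-time trends in incidence, or dependent censoring.
Passing tests therefore demonstrate correctness of the estimators under
stationarity and independent censoring, not robustness to violations of
those assumptions.

## Monte-Carlo problem sizes used by the test suite

The published study surface uses 100 runs of n = 125 per configuration;
the acceptance script and both study-level tests reproduce that size
exactly (mean DISSEs at this size still carry ±10–20% Monte-Carlo wobble
across master seeds, which is why study-level comparisons use ±30%
relative bands).  Unit-level Monte-Carlo checks (parameter recovery, EM
consistency, calibration) use n between 2,000 and 20,000 with fixed seeds.

## Known limitations

* The boundary correction is a documented stand-in for the original
  corrected-NPMLE rule, which the available sources do not restate; the
  plug-in curve's level (and hence DISSE and downstream weights) is
  sensitive to it.
* With several flexible submodels fitted to the same n = 125 dataset, the
  IPCW-Brier objective is nearly flat in α; per-run optimal weights are
  sparse but their location varies run to run, so mean weights carry large
  Monte-Carlo and convention sensitivity even when every individual
  submodel's DISSE is reproduced.
* Administrative censoring truncates the NPMLE support; its plug-in curve
  is 0 beyond the frontier by construction, which is the dominant term in
  its DISSE under heavy administrative censoring.
* Under administrative censoring the Weibull residual likelihood is
  sometimes maximized at implausibly large shapes (a near-uniform residual
  density matching the common censoring cutoff); these are genuine global
  maximizers of the likelihood on those samples, verified against
  quadrature, and they thicken the right tail of the Weibull submodel's
  DISSE distribution at n = 125.
* The likelihood treats ties and zero residual times permissively
  (density terms at t = 0 use the t = 0 value); exact zeros in real data
  usually indicate unit coarsening rather than true zero residuals.
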