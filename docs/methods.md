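# Methods

## Estimands and model

We target the average treatment effect in an external target population,
Δ = E[Y¹ − Y⁰ | S = 0], from IPD of m two-arm RCTs (S = 1..m) plus a
simple random covariate sample from the target (S = 0, no treatments or
outcomes observed). Identification uses, within each study, the usual
consistency, conditional exchangeability and treatment-positivity
conditions of a randomized trial, plus two extension conditions: every
target covariate profile has positive probability of membership in each
study, and — the substantive relaxation that motivates the two-stage
design — the study-specific CATEs at each fixed covariate value are
distributed across studies with mean equal to the target population's
CATE. Under these conditions Δ equals the expectation over studies of the
study-specific transported effects Δₛ, each of which is a weighted
functional of that study's observed data with weights

    w(a, s) = 1{A = a} / e_a(X, s) × p(X, 0) / p(X, s).

The two-stage estimator plugs in estimated propensities, self-normalizes
within each arm of each study (Hájek form; no un-normalized variant is
exposed, since the self-normalized form is invariant to within-arm weight
scaling and much more stable under heavy weight tails), and averages the
study estimates with strictly positive study-level weights. Only equal
weights ship; the combiner accepts arbitrary positive weights through its
interface for sensitivity work.

## Nuisance models

* Treatment: one binomial logistic regression per study (arms may be
  assigned differently across trials). Main effects of all covariates by
  default; a patsy formula string or a column subset can override (e.g.,
  to add a quadratic age term).
* Membership: a single multinomial logistic regression over
  {target, study 1..m}, target as baseline. Fitted probability vectors are
  strictly positive and sum to one per record (checked at 1e-8).
* Fitting is Newton MLE via statsmodels with `tol = 1e-6`, `maxiter = 100`;
  convergence is judged on the library's coefficient-convergence flag, and
  perfect-separation warnings are treated as non-convergence. By default a
  non-converged model raises; `allow_nonconvergence` downgrades to a
  recorded flag.
* Optional stabilizers, both off by default because neither is part of the
  core method: ridge-penalized fits (scikit-learn, intercept unpenalized,
  strength `ridge`) for separation, and symmetric probability truncation
  at (`prob_floor`, 1 − `prob_floor`) for practical positivity failures.
  Membership probabilities are renormalized after truncation.

The pooled comparator reuses the same per-study treatment fits (a pooled
single treatment model would be an equally defensible reading; per-study
fits keep the nuisance estimates identical across comparators so
differences reflect the weighting scheme alone). Membership covariates may
differ from treatment covariates.

## Stratified bootstrap

Each replicate resamples (i) the target sample with replacement at size
n₀, (ii) m studies with replacement with equal probability, (iii) each arm
within each drawn study at its original arm size. A study drawn k times
enters as k distinct relabeled studies, so the replicate always has m
studies, each carrying an equal study-level weight — this preserves the
distribution of the equal-probability study resample. All nuisance models
are refitted per replicate so the SE reflects their estimation
uncertainty (we read the procedure's intent this way; the SE would be
anti-conservative otherwise). Replicate estimates that fail (positivity,
degenerate weights, non-convergence) are recorded as missing and counted,
never dropped silently. Confidence intervals are percentile intervals
with linear interpolation between order statistics (the common "type 7"
quantile definition). Default B = 1000. Per-replicate RNG streams are
spawned from the master seed, so results are bitwise reproducible and
safe to parallelize.

A missing-replicate sensitivity analysis recomputes the interval with all
missing replicates imputed below the minimum (one replicate-SD below), at
the mean of the non-missing estimates, and above the maximum; with no
missing replicates all three intervals equal the primary one.

With few studies (m ≲ 10) the between-study stage has little to resample
and the bootstrap is known to underestimate the SE; interval coverage
should be interpreted cautiously in that regime.

## Synthetic data generator

The generator defines the study conditions the package is validated
under: a single covariate X ~ N(0,1); study membership from a multinomial
logit P(S = s | X) ∝ exp(β_{s,0} + β_{s,1} X) with target baseline;
completely randomized treatment, P(A = 1 | S = s) = 0.5; per-study
coefficient vectors θₛ = (νₛ, γₛ, λₛ, κₛ) ~ N(θ₀, diag(0.5, Σ_γ, 0.5,
Σ_κ)) with θ₀ = (−1, −1, 0.5, −0.5); outcomes Y = ν_S + Aγ_S + Xλ_S +
AXκ_S + ε, ε ~ N(0,1). Both potential outcomes are stored per record
(target rows use θ₀), so the observed outcome equals the potential
outcome of the assigned arm and the empirical target mean of Y¹ − Y⁰ ties
back to the analytic truth Δ = −1 − 0.5·E(X | S = 0).

Sample-size regimes: "large" ≈ 5500 target / 1500 per study on average,
"small" ≈ 200 / 100. The "different" pattern scales expected study sizes
linearly with a largest/smallest ratio of 6 (within the intended 4–10
range); "similar" makes them equal. Presets: Setting 1 (similar sizes,
Σ_γ = 0.1, Σ_κ = 2), Setting 2 (different sizes, same variances), Setting
3 (different sizes, Σ_γ = 2, Σ_κ = 0.1).

Membership intercepts are calibrated so the expected source fractions
match the requested size pattern: iterative proportional updating of the
baseline-relative intercepts on a deterministic stratified normal grid
(midpoint quantiles, 200k points), converging to well inside the 2%
relative tolerance and reducing to the closed form log(q_s/q₀) when all
slopes vanish. The covariate slopes β_{s,1} are a documented
reconstruction — linspace(−1, 0, m) — chosen once to realize the
qualitative design: the conditional center of X increases from study 1 to
study m and the target's center lies at or above all studies. Any slope
vector can be supplied through the configuration. Because variance-level
simulation results are sensitive to the exact slopes, reproductions of
second-moment quantities (EmpSE, MSE, coverage) with the default slopes
agree in magnitude and ordering but not numerically; bias-level
conclusions do not depend on this choice.

The true TATE is computed as γ₀ + κ₀·Ê(X | S = 0) with Ê a 10⁶-draw Monte
Carlo average under the membership model (SE ≈ 0.0005 on Δ).

What the generator does not emulate: multiple or non-normal covariates,
covariate-dependent treatment assignment, non-normal random effects,
missing data, and finite target populations. Passing tests therefore
demonstrate correctness of the machinery under the stated model, not
robustness to real-data violations of it.

At very small sample sizes a realized study can lack an arm; the
generator redraws that study's assignment vector from its own stream
(logged) or errors, per configuration. Per-study random-effect streams
are keyed by study label so enlarging m leaves earlier studies' draws
unchanged.

## Evaluation harness

Per replication the harness simulates, fits, estimates (and optionally
bootstraps) and scores against the analytic truth. Metrics and Monte
Carlo SEs follow standard simulation-study conventions: bias, EmpSE
(ddof = 1), MSE, CI coverage, and the bootstrap-SE relative error
100·(ModSE/EmpSE − 1) with ModSE the root-mean-square of bootstrap SEs.
The relative-error MCSE uses a leave-one-replicate-out jackknife (no
standard closed form exists for this ratio). Missing replicate estimates
are excluded with the rate reported. The identity
MSE = bias² + EmpSE²·(K−1)/K holds exactly and is enforced in tests.

Positivity diagnostics summarize, for each study, the fitted membership
probabilities of target-sample members (mean, SD, range) and flag values
under a configurable floor — the practical check recommended before
trusting study-specific transported estimates.

## Problem sizes in the shipped tests

The default test suite runs reduced-scale versions of the replicated
experiments, chosen as the package's own verification budget: Setting 2
with m = 3 large studies at K = 400 replications and m = 10 at K = 250
(Monte Carlo bands widened ×2 relative to K = 1000), the efficiency
comparison at K = 150 per setting, and a bootstrap-SE calibration check
at m = 10 small studies (40 replications × 80 draws, 30% tolerance
matching the Monte Carlo error of an SE ratio at that scale). Full-scale
runs (K = 1000, B = 1000, nested bootstrap for coverage) are available
through `metatransport evaluate -K 1000 -B 1000`.

## Known limitations

* Equal study-level weights only (variance- or overlap-inspired weights
  are accepted by the combiner but not derived).
* No augmented/outcome-model-based or doubly robust estimators.
* No closed-form variance; the bootstrap is the only uncertainty method,
  and it is optimistic for small m.
* Positivity failures are surfaced (errors, flags, missing replicates),
  not remedied beyond optional truncation/ridge.
* Two treatment arms; complete covariates (an option drops incomplete
  rows with a logged count); no survey weights.
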