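# Methods

## The problem

Electronic-health-record cohorts record an outcome only when a patient
interacts with the healthcare system. Writing `W` for baseline covariates,
`A ∈ {0,1}` for treatment, `Δ ∈ {0,1}` for the monitoring indicator and `Y`
for the binary outcome, the observed unit is `O = (W, A, Δ, ΔY)`: `Y` exists
for everyone but is *recorded* only when `Δ = 1`. Monitoring is typically
*differential* — it depends on both `W` and `A` — so outcome missingness is
informative. The causal estimand throughout is the marginal risk ratio

    Ψ = E[Y(a=1, δ=1)] / E[Y(a=0, δ=1)],

the ratio of counterfactual outcome probabilities had everyone been treated
(resp. untreated) *and* monitored.

Two identification strategies are implemented:

- **restrict** — a complete-case analysis: fit
  `Q̄(a, w) = E(Y | A=a, Δ=1, W=w)` on monitored records and standardize over
  the covariate distribution of the monitored subsample. Its large-sample
  limit (`restrict_target` in the truth calculator) differs from `Ψ` whenever
  monitoring depends on covariates that also modify the treatment effect.
- **joint intervention** — treat `(A, Δ)` as a joint intervention and
  standardize the same `Q̄` over the *full* cohort's covariates. Under
  exchangeability given `W` (which the simulator satisfies by construction,
  since `Δ ⟂ Y | A, W`) this identifies `Ψ`.

Both identifications are computed as ratios of standardized means. The
expectation-of-ratio variant `E[ Q̄(1,W)/Q̄(0,W) ]` is also computed and
exposed on `TrueEstimands` as a diagnostic (`mean_of_ratios*`), but it is a
different parameter and is not used anywhere as a target.

## The structural simulator

Three logistic structural equations generate a cohort in the order
`W → A → (M) → Y(1), Y(0) → Y = Y(A) → Δ → mask Y when Δ = 0`:

    logit P(A = 1 | W)        = a₀ + aᵀW
    logit P(Δ = 1 | A, W)     = d₀ + dᵀW + d_A A
    logit P(Y = 1 | A, W)     = b₀ + b_A A + bᵀW + (cᵀW)A + sᵀW²

Counterfactual outcomes share one uniform draw per patient, so factual
consistency `Y = Y(A)` holds record by record, and the hidden columns
`Y1, Y0` are exactly the potential outcomes under `(a, δ=1)`. All structural
probabilities are clamped to `[10⁻⁶, 1−10⁻⁶]` before Bernoulli draws —
numeric safety that does not materially change any law used here.
An optional post-treatment binary mediator `M` (logit linear in `A` and `W`)
can be enabled, in which case the outcome logit gains `γ_M · M`; the truth
calculator integrates `M` out analytically.

Estimators can never touch the hidden columns: `CohortTable.observed_frame()`
returns only `W, A, Δ, Y` (with `Y` missing when `Δ = 0`) and is the only
accessor the estimation layer uses; `counterfactual_frame()` exists for truth
calculators and for the mediator-conditioning demonstration, which mimics a
registry that *samples* patients on diagnostic status.

**True estimands.** With all-binary covariates, `ψ₁`, `ψ₀` and the restrict
target are computed by exhaustive summation over the `2^p` covariate support
(the restrict standardization weights each cell by
`f(w)·P(Δ=1|w)`, with `P(Δ=1|w)` marginalized over treatment). With a
continuous covariate, Monte-Carlo integration with 10⁶ draws and a dedicated
fixed seed is used; at that size the integration error is far below every
tolerance in the package.

### Scenario presets

Coefficients are frozen in `scenario_preset`; they were chosen to make each
scenario's qualitative structure unambiguous at desk scale and then verified
against the exhaustive-sum oracle:

- **figure1** (differential monitoring): three binary covariates; monitoring
  loads on `W1, W2` and on treatment; the outcome has a strong `A×W1`
  interaction. True `Ψ ≈ 1.066`, restrict target `≈ 0.959` — a log-scale gap
  of ≈ 0.105, so the complete-case analysis is not merely biased but lands on
  the wrong side of the null.
- **figure3_null** (true null, nonlinear confounding): treatment coefficient
  of the outcome equation exactly zero, so `Ψ = 1` identically; the outcome
  depends on `W3²` for a standard-normal `W3` that also drives treatment.
  A main-terms logistic outcome model is therefore misspecified in a way
  that does not average out (the asymptotic log-RR bias of the parametric
  plug-in is ≈ 0.07), while any library containing a squared-terms logistic
  can fit it exactly.
- **mediator_conditioning**: the treatment affects the outcome only through
  a binary mediator (`γ_A = 1.5` on the mediator logit, `γ_M = 1.8` on the
  outcome logit, no direct effect). Conditioning on `M = 1` — as
  diagnosis-sampled registries implicitly do — removes the mediated effect
  and biases the estimate toward the null by ≈ −0.36 on the log scale.
- **random_monitoring**: `Δ` is a fair-ish coin (`P(Δ=1) = 0.7`) independent
  of everything; restrict and intervene targets then coincide exactly, which
  the truth calculator and estimators both reproduce — a control scenario
  used by the collapse tests.

## Nuisance estimation

The learner library is deliberately small and dependency-light: main-terms
logistic, logistic with all pairwise interactions, logistic with squared
terms for continuous columns, a k-nearest-neighbour probability smoother
(k = 50, standardized features), a depth-1 gradient-boosting option, a
constant-rate fallback, and a *saturated* learner that returns exact
empirical cell means over the discrete feature support (used by the oracle
tests; unseen cells fall back to the overall mean). Logistic fits carry a
ridge penalty of 10⁻⁶ purely as separation protection.

The **super learner** runs stratified V-fold cross-validation (default
V = 5, fold permutation fixed by the learner-spec seed), scores members by
out-of-fold binomial log-loss — the proper scoring rule for probability
nuisances — and solves for convex weights minimizing the blended log-loss
with SLSQP on the probability simplex (analytic gradient; 500 iterations,
ftol 10⁻¹²). Because every vertex of the simplex is feasible, the optimum
can never exceed the best single member's cross-validated risk; if the
optimizer ever returns a worse point (a numerical pathology), the best
vertex is used instead, so the guarantee is unconditional. Weights,
per-member risks and the ensemble risk are retained on the fitted object.
The default library is `{main-terms, pairwise interactions, squared terms,
k-NN}` — a stand-in, since no canonical library is prescribed for this kind
of analysis.

## Estimators

All five estimators consume only the observed frame. `Q̄` is always fitted on
monitored records; the treatment propensity `gA(w) = P(A=1|W=w)` and the
monitoring propensity `gΔ(a, w) = P(Δ=1|A=a, W=w)` on all records.
Propensities are truncated to `[bound, 1−bound]` (default 0.01) and the
share of records whose *weight denominators* fall below the bound is
reported; above 5% a `PositivityWarning` is raised. A monitoring propensity
near one is benign and not flagged.

- **unadjusted**: crude ratio of event rates among monitored patients, SE
  from the standard 2×2 log-RR formula. Zero-event arms raise an error; a
  0.5 continuity correction exists behind a flag for this estimator only.
- **restrict**: plug-in standardization of `Q̄` over monitored covariates.
  SE by the influence-curve approximation of the plug-in (treating `Q̄` as
  correctly specified), which needs a treatment propensity *within* the
  monitored subsample — main-terms logistic by default. No bootstrap path
  is provided.
- **intervene g-computation**: same `Q̄`, standardized over all records.
  The propensities enter only the influence-curve SE and diagnostics.
- **intervene IPW**: weights `1{A=a, Δ=1} / (gA(a|W) gΔ(1|a,W))`, Hájek
  (within-arm normalized) by default, Horvitz–Thompson behind a flag. With
  constant propensities the Hájek form reduces exactly to the stratified
  means.
- **intervene TMLE**: per arm, one logistic fluctuation of `Q̄` with offset
  `logit Q̄` and clever covariate `H_a = 1{A=a, Δ=1}/(gA(a|W) gΔ(1|a,W))`,
  fitted by IRLS (statsmodels GLM; tol 10⁻¹²). `Q̄` is clipped to
  `[10⁻⁶, 1−10⁻⁶]` before the logit. The updated predictions at
  `(a, δ=1)` are averaged over the full cohort. The empirical mean of each
  arm's estimated efficient influence curve is checked against
  `10⁻⁴·sd/√n` and reported in the diagnostics; with saturated nuisances on
  discrete covariates the initial fit already solves the score equation, the
  fluctuation coefficient is zero and TMLE coincides with the g-computation
  plug-in. If every outcome in a fluctuation cell is identical the IRLS
  coefficient diverges; a capped grid search for the score-equation root on
  `ε ∈ [−10, 10]` is used instead.

Inference for every adjusted estimator is the delta method on
`log(ψ̂₁/ψ̂₀)`: the per-record contribution is `D₁/ψ̂₁ − D₀/ψ̂₀`, whose
empirical variance over n gives the squared SE — the covariance between the
two arms' influence curves is thereby included. Wald intervals use
standard-normal quantiles (nominal level 0.95 by default), so the
interval/test duality with the two-sided Wald p-value is exact. Nuisances
are fitted on the full sample; no cross-fitting option is provided.

## Monte-Carlo experiments

Replicate `i` of any experiment uses seed `(master_seed + i) mod 2³¹`,
logged per replicate; every experiment is byte-reproducible from the master
seed. Replicates whose estimation fails (degenerate cells) are counted and
excluded, never imputed. Summaries report mean/SD of the log risk ratio,
bias and RMSE against the oracle truth, CI coverage, null-rejection rate and
mean interval width.

Default problem sizes — 200 replicates, cohorts of 1,000–20,000 — were
chosen as desk-scale settings at which every scenario's qualitative contrast
is far larger than the Monte-Carlo noise (3 binomial SDs of a 95% coverage
estimate over 200 replicates is ±4.6 points). The bias experiment runs
unadjusted, restrict, g-computation and TMLE at n = 5,000; the Type-1 sweep
runs the misspecified main-terms parametric g-computation against
TMLE-with-ensemble at n ∈ {1,000, 5,000, 20,000}; the mediator demonstration
contrasts mediator-conditioned and full-cohort g-computation at n = 20,000.
In the bias and Type-1 experiments the interaction/squared structure of the
generating equations lies inside the span of the flexible learners used, so
the joint-intervention estimators are consistent there by construction —
which is what makes the contrast with restrict and with the rigid parametric
model interpretable.

## What the simulator does and does not emulate

The generator reproduces the *structure* that makes differential monitoring
dangerous — confounded treatment, monitoring driven by covariates and
treatment, effect modification, nonlinear confounding, a post-treatment
mediator — with a handful of covariates and single-shot monitoring. Real
EHR cohorts add high-dimensional covariates, repeated monitoring over time,
interval censoring, measurement error in the outcome definition and
cohort-entry (index-time) ambiguities, none of which are modelled. Passing
tests therefore certify the estimators' behaviour under the stated
structural assumptions, not their performance on any particular real
database.

## Known limitations

- Monitoring is a single binary indicator; longitudinal monitoring
  schedules, survival outcomes and interval-censoring positivity problems
  are out of scope.
- The restrict SE treats the outcome regression as correctly specified;
  under misspecification its intervals inherit the plug-in's optimism (no
  bootstrap alternative is provided).
- The super-learner library is small by design; it spans the
  misspecifications used in the shipped scenarios but is not a general
  substitute for a rich library.
- Probability truncation is symmetric; the upper truncation of a monitoring
  propensity slightly inflates weights when monitoring is near-certain
  (at most by the bound itself).
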