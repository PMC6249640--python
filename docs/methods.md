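# Methods

## Model overview

`coxianreg` implements a two-stage analysis of a repeatedly measured
biomarker and a survival outcome.

**Stage 1 — longitudinal model.** The biomarker for subject *i* at visit
time *t* (months) follows a linear mixed effects model

y_ij = x_ij'β + b_i0 + b_i1 t_ij + ε_ij,  b_i ~ N(0, D),  ε_ij ~ N(0, σ²),

with a subject-specific random intercept `b0` and slope `b1` (bivariate
normal with 2×2 covariance `D`) and independent Gaussian residuals
(`R_i = σ² I`; no serial-correlation options are offered). Estimation is
maximum likelihood by default — REML is a flag — so that likelihood-ratio
tests on fixed effects remain valid. Continuous fixed covariates other than
time are centred about their sample means and the centring constants are
stored with the estimates, making downstream inputs reproducible. Random
effects are predicted by the empirical BLUP

b̂_i = D Z_i' V_i⁻¹ (y_i − X_i β̂),  V_i = Z_i D Z_i' + σ² I,

which shrinks each subject's raw deviation toward zero in proportion to the
information their visits carry.

**Stage 2 — survival model.** Survival times follow a Coxian phase-type
distribution: a continuous-time Markov chain on ordered transient phases
1..n, entered at phase 1, moving onward at rates λ_k and absorbing (the
event) at rates μ_k, with λ_n = 0. The density, survivor, hazard and
cumulative hazard are

f(t) = p e^{Qt} q,  S(t) = p e^{Qt} 1,  h(t) = f(t)/S(t),  H(t) = −log S(t),

with Q the bidiagonal transient generator, p = (1,0,…,0) and q = μ. The
probability of exiting from phase k is
π_k = (μ_k/σ_k) ∏_{j<k} (λ_j/σ_j) with σ_k = λ_k + μ_k, and ordered event
times are partitioned into phase cohorts in the ratio π_1:…:π_n with the
cumulative cut at ⌊M Σ_{k≤g} π_k⌋ and the remainder assigned to the last
phase (blocks whose expected size is below one observation may be empty).

In the regression model each subject's rates are scaled by a common
rate-of-flow factor exp{−b0 α1 − b1 t α2}: factors above one mean faster
progression through the latent phases. The subject likelihood evaluates
this factor at the subject's own event (or censoring) time; because a
uniformly scaled generator is a time change, the event contribution is
c_i f0(c_i t_i) and the censored contribution S0(c_i t_i), which makes the
likelihood cheap to evaluate at any cohort size.

## Numerical choices

* **Density evaluation.** The analytic partial-fraction form
  f(t) = Σ_k a_k σ_k e^{−σ_k t} (and its term-wise integral
  S(t) = Σ_k a_k e^{−σ_k t}) is the fast path. Total rates tied within
  1e−9 relative make the expansion undefined and route evaluation to the
  matrix exponential (scipy's scaling-and-squaring Padé `expm`), as do
  individual points where cancellation drives the analytic value out of
  range. Near-tied rates (e.g. a gap of order 1e−9 relative, as in the
  bundled three-phase reference rates where μ1 ≈ 9×10⁻¹¹) keep the analytic
  form admissible but limit its agreement with the matrix form to roughly
  1e−5 relative — double-precision cancellation, not model error; the
  matrix form is the arbiter wherever the two disagree.
* **Analytic survivor.** S(t) is obtained by integrating the analytic
  density term by term; it shares the coefficients a_k with the density and
  is verified against the matrix form p·e^{Qt}·1 in the test suite.
* **Underflow guards.** Log-density/log-survivor contributions are floored
  at 1e−300 during optimisation. Where S(t) underflows, the hazard returns
  the final-phase rate μ_n (its limit whenever the final phase is the
  slowest, the usual case since λ_n = 0) and the cumulative hazard switches
  to the exact asymptote of −log S — linear in t with the slowest mode's
  rate and amplitude, which reduces to μ·t exactly for the one-phase
  (exponential) model.
* **Optimisation.** The (2n−1) rates are searched as unconstrained
  log-rates (a floor of e⁻³⁰ stands in for an exact zero), with α appended
  unconstrained in the regression model. Nelder–Mead multi-start: default
  50 restarts drawn log-uniformly on [0.1/t̄, 10/t̄] (t̄ the mean observed
  time), coarse per-restart tolerances, and a tight polish (fatol 1e−12) of
  the winner — the fit is strongly start-dependent, hence the restarts. The
  regression fit adds a warm start at the covariate-free optimum with
  α = 0; phase-number selection seeds each n-phase search from the
  (n−1)-phase solution padded with a tiny extra rate, which enforces
  likelihood nesting across n.
* **Phase-number selection.** Phases are added sequentially from n = 1;
  the search stops when the 2-df LRT against n−1 phases is non-significant
  *and* the AIC worsens; otherwise the trace continues to `max_phases` and
  the AIC minimiser is chosen. Two caveats are deliberate: the χ²₂
  reference ignores the boundary non-regularity of rates at zero (making
  the LRT conservative), while the AIC channel keeps an extra phase
  whenever the log-likelihood gain exceeds 2 — under a null (exponential)
  truth this liberal channel admits an extra phase in roughly 15–30% of
  replicates. Users wanting stricter parsimony should read the full trace
  (all of loglik/AIC/BIC/LRT are recorded) rather than `chosen_n` alone.
* **Bootstrap.** Nonparametric subject-level resampling; each replicate is
  refitted by a single Nelder–Mead run warm-started at the full-data
  optimum with coarse tolerances (the replicates only feed a spread
  estimate). Reported intervals are the normal approximation
  e^{−α̂} ± 1.96·se with percentile intervals stored alongside; a factor is
  "significant" iff 1 lies outside the closed interval. Replicates that
  fail to produce a finite optimum are dropped and counted; more than 20%
  dropped flags a warning status.
* **Rate identifiability and canonical form.** A Coxian's density fixes
  its exponential modes and weights but not the phase labelling, so
  different rate vectors can describe one distribution.
  `canonical_form` re-solves the exit probabilities against the
  hypoexponential basis taken in decreasing total-rate order and rebuilds
  (λ, μ), giving a unique representative; rate-level comparisons (e.g.
  recovery experiments) are made in this form. Rates are *practically*
  identifiable only when the total rates are well separated and every
  phase carries appreciable exit mass; outside that regime fits should be
  compared as densities, not rate vectors.

## Individual-specific curves

Personalised survivor and hazard curves scale the baseline through the
time-change identities S_i(t) = S0(c t) and h_i(t) = c·h0(c t). Two
conventions are offered for the factor c. `scaling_time=τ` freezes
c = exp{−b0 α1 − b1 τ α2} at the subject's biomarker observation time τ —
the convention used for reported personalised curves, under which the
hazard converges to the personalised final-phase rate c·μ_n.
`scaling_time=None` re-evaluates the factor at every plotted t (the literal
time-varying exponent); with a nonzero slope deviation this curve's late
tail is driven by the extrapolated factor and its hazard does *not*
converge to c·μ_n. The frozen mode is the default recommendation for
communication; the pointwise mode matches the likelihood's convention.

Note the likelihood itself is a *profile* evaluation: the factor at the
subject's own event time scales the whole trajectory, so the per-subject
"density" is not normalised in t. This is the published estimator and is
implemented literally, not silently corrected. One measurable consequence
(see the recovery experiments): when data are generated under truly
time-varying rates, the estimator attenuates α2 (by roughly 0.05–0.09 at
the default study conditions) and, if censored subjects are present, the
factor extrapolated to the censoring time inflates α1; with complete
mortality follow-up the α1 bias largely vanishes. A second consequence:
subjects with a rising biomarker (b1 > 0 with α2 > 0) have integrable
hazards and hence a defective survival distribution — a fraction of such
subjects never absorbs, which mirrors the clinical reading that an
improving biomarker defers the event indefinitely under this model.

## Synthetic cohorts

The generator emulates the joint structure the method assumes, at the study
conditions of a haemodialysis CKD registry: 577 subjects; per-subject visit
counts from a shifted negative binomial (r = 2) calibrated to mean 18,
truncated to [2, 84], with monthly visits; haemoglobin-like trajectories
(β intercept 10.5 g/dL, small negative time trend, one continuous and one
binary covariate); random-effect covariance D = [[1.5, −0.181], [−0.181,
0.04]] giving the reported intercept–slope correlation of −0.74; residual
variance 0.5; baseline three-phase rates λ = (0.060, 0.467, 0),
μ = (9.02×10⁻¹¹, 0.435, 0.060) per month; covariate effects
α = (0.246, 0.156); administrative censoring at 116 months (the registry's
window). The longitudinal truth (β, D, σ²) is a synthetic stand-in chosen
for realistic haemoglobin trajectories — no registry values are available
for it.

Survival times honour the time-varying factor by freezing it on a 0.1-month
grid (a config knob) with exact competing-exponential draws within each
step, redrawn at step boundaries (valid by memorylessness). Longitudinal
records after the survival time are dropped, deliberately reproducing the
informative-dropout regime of registry data: short survivors contribute
fewer biomarker measurements, which slightly biases Stage 1 — the
motivation for joint-likelihood approaches, which are out of scope here.

What passing tests on these cohorts do **not** show: robustness to
non-Gaussian biomarker noise, serial correlation within subjects, visit
schedules correlated with health state, measurement error in the covariates,
or real registry covariate distributions (ferritin, EPO regimes and the
like are replaced by generic continuous/binary stand-ins).

## Test and experiment sizes

Simulation experiments are sized to run on a single CPU in minutes: the
cross-oracle battery uses 24 parameter sets over 1–4 phases; sampling
calibration uses 10⁵ trajectories; the three-phase rate-recovery experiment
uses 20 seeds × 5000 uncensored times with 10 restarts, at a truth with
total rates (3.0, 0.6, 0.1)/month and equal exit mass per phase (the
identifiable regime); regression recovery uses 10 seeds × 1500 subjects
with complete mortality follow-up (administrative cap 600 months); the
end-to-end two-stage experiment uses 10 seeds × 577 subjects with a B = 200
bootstrap. Defaults in the API are larger (50 restarts, B = 500).

## Known limitations

* The Eq.-style profile likelihood is not a normalised density in t
  (documented above); joint estimation of both stages is not offered.
* Covariate effects are common to all transitions; per-transition
  coefficients are not supported.
* Only the Coxian subclass is supported — no general phase-type
  generators, parallel/Erlang branches, or discrete-time variants.
* The two-stage pipeline wires only (b0, b1·t) as Stage-2 covariates; the
  general x'α path exists in the likelihood code but is not exposed in the
  workflow.
* Stage 1 inherits the informative-dropout bias of fitting an LME to
  trajectories truncated by death.
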