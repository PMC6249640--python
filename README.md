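# coxianreg

Two-stage joint analysis of a longitudinal biomarker and a survival
outcome, built around the **Coxian phase-type regression model**. It is
aimed at biostatisticians analysing chronic-disease registries — the
motivating setting is chronic kidney disease, where haemoglobin is a
repeatedly measured biomarker and the outcome is death on haemodialysis —
who want more than a hazard ratio: which latent disease stages the cohort
passes through, how fast each individual flows through them, and
personalised survivor and hazard curves.

## The model

**Stage 1.** A linear mixed effects model for the biomarker,

y_ij = x_ij'β + b_i0 + b_i1·t_ij + ε_ij,  b_i ~ N(0, D),  ε_ij ~ N(0, σ²),

yields subject-level intercept and slope deviations (b_i0, b_i1), predicted
by the empirical BLUP b̂_i = D Z_i'V_i⁻¹(y_i − X_i β̂). These deviations are
a proxy for the subject's unobserved profile.

**Stage 2.** Survival times follow a Coxian phase-type distribution — a
Markov chain on ordered transient phases 1..n entered at phase 1, with
onward rates λ_k and absorption (event) rates μ_k, λ_n = 0:

f(t) = p e^{Qt} q,  S(t) = p e^{Qt} 1,  h(t) = f(t)/S(t),

with Q bidiagonal (diagonal −(λ_k+μ_k), superdiagonal λ_k). The phases can
be read as latent disease stages; π_k = (μ_k/(μ_k+λ_k))·∏_{j<k} λ_j/(μ_j+λ_j)
is the probability of dying from stage k. The Stage-1 deviations enter as
covariates scaling every rate by the subject's **rate-of-flow factor**

exp{−b_i0 α1 − b_i1 t α2},

so a factor of 2 means progressing through all stages twice as fast as the
population average. Rates and α are estimated jointly by multi-start
Nelder–Mead maximum likelihood; the number of phases is chosen by
sequential likelihood-ratio tests and AIC; standard errors of the reported
factors e^{−α} come from a subject-level bootstrap.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

A fitted three-phase model for a haemodialysis cohort of 577 subjects has
rates λ = (0.060, 0.467, 0), μ = (9.02×10⁻¹¹, 0.435, 0.060) per month and
coefficients α = (0.246, 0.156). Consider a subject whose haemoglobin
starts 3.85 g/dL below the population average but rises 0.081 g/dL/month
faster, observed 6.72 months after starting dialysis:

```python
import numpy as np
from coxianreg import (
    CoxianParameters, RegressionCoefficients, SubjectRandomEffects,
    absorption_probabilities, phase_time_bounds, rate_scaling_factor,
    sample_absorption_times, scaled_parameters, survivor,
)

rates = CoxianParameters(lambdas=np.array([0.060, 0.467, 0.0]),
                         mus=np.array([9.02e-11, 0.435, 0.060]))
coeffs = RegressionCoefficients(alpha1=0.246, alpha2=0.156)
subject = SubjectRandomEffects(143, b0=-3.850, b1=0.081)

factor = rate_scaling_factor(subject, 6.72, coeffs)
print(f"rate-of-flow factor: {factor:.3f}")

pis = absorption_probabilities(rates).pis
print("absorption probabilities:", np.array2string(pis, precision=3))

print(f"personalised final-phase hazard: {scaled_parameters(rates, factor).mus[-1]:.3f}")

times = np.sort(sample_absorption_times(rates, 577, seed=1))
print("phase partition:", phase_time_bounds(absorption_probabilities(rates), times).bounds)

print(f"baseline 5-year survival: {survivor(rates, 60.0):.3f}")
print(f"subject-143 5-year survival: {survivor(scaled_parameters(rates, factor), 60.0):.3f}")
```

prints

```text
rate-of-flow factor: 2.368
absorption probabilities: [1.503e-09 4.823e-01 5.177e-01]
personalised final-phase hazard: 0.142
phase partition: ((0, 0), (0, 278), (278, 577))
baseline 5-year survival: 0.083
subject-143 5-year survival: 0.001
```

Read: this subject progresses 2.368× faster than the population average, so
their long-run hazard is 0.06 × 2.368 = 0.142 deaths/month instead of
0.06. Essentially nobody dies from stage 1 (π₁ ≈ 1.5×10⁻⁹); about 48% of
deaths come from stage 2 and 52% from stage 3, so of 577 ordered death
times the first 278 are attributed to stage-2 exits. The subject's five-year
survival probability collapses from the population-average 8.3% to 0.1%.

## Command line

The same workflow is scriptable:

```sh
coxianreg simulate --n-subjects 577 --seed 1 --out cohort/
coxianreg run --longitudinal cohort/longitudinal.csv \
              --survival cohort/survival.csv \
              --fixed x_cont --fixed x_bin \
              --max-phases 4 --seed 1 --out results/
```

`run` executes mixed model → BLUPs → phase selection → Coxian regression →
bootstrap, writing `results.json`, survivor/hazard/cumulative-hazard curve
tables and a text report. `simulate`, `fit-lme`, `fit-coxian`,
`fit-regression`, `bootstrap` and `curves` expose the individual stages;
`--effects` lets `run` skip Stage 1 with a precomputed effects table.

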