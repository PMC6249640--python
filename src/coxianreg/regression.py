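"""Coxian phase-type regression with random-effect covariates.

Subject-level covariates scale every transition and absorption rate by a
common multiplicative rate-of-flow factor ``exp(-x_i' alpha)``.  In the
two-stage workflow the covariates are the Stage-1 predicted random effects:
an intercept deviation ``b0`` (time-fixed) and a slope deviation entering as
the product ``b1 * t``, so the factor for subject ``i`` observed at time
``t`` is ``exp(-b0_i alpha1 - b1_i t alpha2)``.  Factors above 1 mean faster
flow through the latent disease phases (and so shorter survival); factors
below 1 mean slower flow.

The likelihood evaluates each subject's density under their own scaled
generator, with the scaling exponent taken at the subject's event time.
Because a uniformly scaled generator is a time change, the subject density
reduces to ``c_i * f0(c_i t_i)`` and the censored contribution to
``S0(c_i t_i)``, where ``f0``/``S0`` are the baseline density and survivor
-- this identity makes the likelihood cheap to evaluate.  Standard errors of
the reported factors ``e^{-alpha}`` come from a nonparametric subject-level
bootstrap with normal-approximation 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (
    CoxianParameters,
    _density_survivor_arrays,
    hazard,
    survivor,
)
from .inference import (
    ConvergenceError,
    FitResult,
    ModelSelectionTrace,
    SurvivalSample,
    _multistart,
    _pack_rates,
    _padded_start,
    _random_starts,
    _unpack_rates,
    _PENALTY,
    fit_coxian,
)

__all__ = [
    "RegressionCoefficients",
    "SubjectRandomEffects",
    "RegressionFitResult",
    "BootstrapSummary",
    "rate_scaling_factor",
    "scaled_parameters",
    "regression_loglikelihood",
    "fit_coxian_regression",
    "select_phases_regression",
    "bootstrap_inference",
    "normal_ci",
    "significance_from_ci",
    "individual_survivor",
    "individual_hazard",
]


@dataclass(frozen=True)
class RegressionCoefficients:
    """Effects of the intercept deviation (``alpha1``) and of the
    slope-by-time product (``alpha2``) on the log rate-of-flow factor."""

    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha1) and np.isfinite(self.alpha2)):
            raise ValueError("coefficients must be finite")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2])


@dataclass(frozen=True)
class SubjectRandomEffects:
    """One subject's intercept/slope deviations from the population mean."""

    subject_id: object
    b0: float
    b1: float


@dataclass(frozen=True)
class RegressionFitResult:
    """Jointly estimated baseline rates and covariate coefficients."""

    baseline: CoxianParameters
    coefficients: RegressionCoefficients
    loglik: float
    aic: float
    bic: float
    n_restarts: int
    best_start_index: int
    converged: bool
    seed: int

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.to_config(),
            "alpha1": self.coefficients.alpha1,
            "alpha2": self.coefficients.alpha2,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_restarts": self.n_restarts,
            "best_start_index": self.best_start_index,
            "converged": self.converged,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class BootstrapSummary:
    """Bootstrap SEs and 95% normal CIs for the factors ``e^{-alpha}``."""

    B: int
    point_exp_alpha1: float
    point_exp_alpha2: float
    se_exp_alpha1: float
    se_exp_alpha2: float
    ci_exp_alpha1: tuple
    ci_exp_alpha2: tuple
    percentile_ci_exp_alpha1: tuple
    percentile_ci_exp_alpha2: tuple
    replicate_estimates: pd.DataFrame = field(repr=False)
    n_dropped: int
    status: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "point_exp_alpha1": self.point_exp_alpha1,
            "point_exp_alpha2": self.point_exp_alpha2,
            "se_exp_alpha1": self.se_exp_alpha1,
            "se_exp_alpha2": self.se_exp_alpha2,
            "ci_exp_alpha1": list(self.ci_exp_alpha1),
            "ci_exp_alpha2": list(self.ci_exp_alpha2),
            "percentile_ci_exp_alpha1": list(self.percentile_ci_exp_alpha1),
            "percentile_ci_exp_alpha2": list(self.percentile_ci_exp_alpha2),
            "n_dropped": self.n_dropped,
            "status": self.status,
            "seed": self.seed,
        }


def rate_scaling_factor(
    effects: SubjectRandomEffects, t, coeffs: RegressionCoefficients
):
    """Multiplicative rate-of-flow factor ``exp(-b0 a1 - b1 t a2)``.

    Equals 1 for the baseline subject (``b0 = b1 = 0``), whose biomarker
    trajectory matches the population average.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    out = np.exp(-effects.b0 * coeffs.alpha1 - effects.b1 * t_arr * coeffs.alpha2)
    return float(out) if np.ndim(t) == 0 else out


def scaled_parameters(baseline: CoxianParameters, factor: float) -> CoxianParameters:
    """All transition and absorption rates multiplied by a common factor.

    The Coxian structure is preserved, and since the absorption
    probabilities depend only on rate ratios they are unchanged.
    """
    return baseline.scaled(factor)


def _effects_frame(effects) -> pd.DataFrame:
    """Normalise effects input (DataFrame or iterable of records) to a frame
    indexed by subject id."""
    if isinstance(effects, pd.DataFrame):
        df = effects
    else:
        df = pd.DataFrame(
            [{"id": e.subject_id, "b0": e.b0, "b1": e.b1} for e in effects]
        )
    missing = {"id", "b0", "b1"} - set(df.columns)
    if missing:
        raise ValueError(f"effects table missing columns: {sorted(missing)}")
    return df.set_index("id")


def _scale_covariates(sample: SurvivalSample, effects) -> np.ndarray:
    """Design matrix of the scaling exponent: columns (b0_i, b1_i * t_i)."""
    df = _effects_frame(effects)
    absent = [sid for sid in sample.subject_ids if sid not in df.index]
    if absent:
        raise KeyError(f"no random-effects record for subject(s): {absent[:5]}")
    sub = df.loc[pd.Index(sample.subject_ids)]
    return np.column_stack(
        [sub["b0"].to_numpy(), sub["b1"].to_numpy() * sample.times]
    )


def _regression_loglik_arrays(lambdas, mus, alpha, times, events, X):
    """Log-likelihood with per-subject uniform rate scaling.

    ``c_i = exp(-X_i alpha)``; events contribute ``log c_i + log f0(c_i t_i)``
    (density of the scaled generator), censored subjects ``log S0(c_i t_i)``.
    """
    expo = X @ alpha
    if np.any(np.abs(expo) > 500):
        return -np.inf
    c = np.exp(-expo)
    u = c * times
    f0, S0 = _density_survivor_arrays(lambdas, mus, u)
    ev = events == 1
    terms = np.empty(times.size)
    terms[ev] = np.log(c[ev]) + np.log(np.maximum(f0[ev], 1e-300))
    terms[~ev] = np.log(np.maximum(S0[~ev], 1e-300))
    return float(terms.sum())


def regression_loglikelihood(
    baseline: CoxianParameters,
    coeffs: RegressionCoefficients,
    sample: SurvivalSample,
    effects,
) -> float:
    """Regression log-likelihood; reduces to the plain Coxian likelihood at
    ``alpha = 0``.  Raises ``KeyError`` naming any subject without a matching
    random-effects record."""
    X = _scale_covariates(sample, effects)
    return _regression_loglik_arrays(
        baseline.lambdas, baseline.mus, coeffs.as_array, sample.times, sample.events, X
    )


def _fit_regression_arrays(
    times, events, X, n_phases, n_restarts, seed, extra_starts=None,
    warm_plain: FitResult | None = None,
):
    n = n_phases
    p = X.shape[1]

    def objective(z):
        x, alpha = z[: 2 * n - 1], z[2 * n - 1 :]
        if np.any(x > 15) or np.any(x < -40) or np.any(np.abs(alpha) > 50):
            return _PENALTY
        lams, mus = _unpack_rates(x, n)
        ll = _regression_loglik_arrays(lams, mus, alpha, times, events, X)
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    rng = np.random.default_rng(seed)
    rate_starts = _random_starts(rng, n_restarts, 2 * n - 1, times.mean())
    alpha_starts = rng.normal(0.0, 0.2, size=(n_restarts, p))
    starts = [np.concatenate([r, a]) for r, a in zip(rate_starts, alpha_starts)]
    if warm_plain is not None:
        starts.append(np.concatenate([_pack_rates(warm_plain.params), np.zeros(p)]))
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    z, negll, idx, ok = _multistart(objective, starts)
    lams, mus = _unpack_rates(z[: 2 * n - 1], n)
    return lams, mus, z[2 * n - 1 :], -negll, idx, ok, len(starts)


def fit_coxian_regression(
    sample: SurvivalSample,
    effects,
    n_phases: int,
    n_restarts: int = 50,
    seed: int = 0,
    extra_starts=None,
) -> RegressionFitResult:
    """Joint MLE of the baseline log-rates and ``(alpha1, alpha2)``.

    Multi-start Nelder-Mead as in the plain fit, plus one warm start taken
    from the covariate-free Coxian fit with ``alpha = 0``.  Deterministic
    given ``seed``.
    """
    if n_phases < 1:
        raise ValueError("n_phases must be at least 1")
    X = _scale_covariates(sample, effects)
    warm = fit_coxian(sample, n_phases, n_restarts=max(n_restarts // 2, 1), seed=seed)
    lams, mus, alpha, ll, idx, ok, n_starts = _fit_regression_arrays(
        sample.times, sample.events, X, n_phases, n_restarts, seed,
        extra_starts=extra_starts, warm_plain=warm,
    )
    k = 2 * n_phases - 1 + X.shape[1]
    return RegressionFitResult(
        baseline=CoxianParameters(lams, mus),
        coefficients=RegressionCoefficients(float(alpha[0]), float(alpha[1])),
        loglik=ll,
        aic=-2 * ll + 2 * k,
        bic=-2 * ll + k * np.log(sample.n),
        n_restarts=n_starts,
        best_start_index=idx,
        converged=ok,
        seed=seed,
    )


def select_phases_regression(
    sample: SurvivalSample,
    effects,
    max_phases: int,
    alpha_level: float = 0.05,
    n_restarts: int = 50,
    seed: int = 0,
) -> ModelSelectionTrace:
    """Phase-number selection for the regression model.

    Same sequential LRT-and-AIC stop rule as the covariate-free selection,
    with the parameter count ``(2n - 1) + 2``.  The LRT between ``n - 1``
    and ``n`` phases still compares two extra rate parameters (2 df).
    """
    if max_phases < 2:
        raise ValueError("max_phases must be at least 2")
    trace = ModelSelectionTrace()
    prev: RegressionFitResult | None = None
    for n in range(1, max_phases + 1):
        extra = None
        if prev is not None:
            plain = FitResult(
                params=prev.baseline, loglik=0, aic=0, bic=0, n_restarts=0,
                best_start_index=0, converged=True, seed=0,
            )
            extra = [
                np.concatenate([_padded_start(plain), prev.coefficients.as_array])
            ]
        try:
            fit = fit_coxian_regression(
                sample, effects, n, n_restarts=n_restarts, seed=seed + n,
                extra_starts=extra,
            )
        except (ConvergenceError, RuntimeError) as err:
            trace.records.append({"n_phases": n, "failed": True, "error": str(err)})
            continue
        rec = {
            "n_phases": n,
            "failed": False,
            "loglik": fit.loglik,
            "aic": fit.aic,
            "bic": fit.bic,
            "fit": fit,
        }
        if prev is not None:
            stat = max(2.0 * (fit.loglik - prev.loglik), 0.0)
            rec["lrt_stat"] = stat
            rec["lrt_p"] = float(stats.chi2.sf(stat, df=2))
            if rec["lrt_p"] > alpha_level and fit.aic > prev.aic:
                trace.records.append(rec)
                trace.chosen_n = prev.baseline.n_phases
                return trace
        trace.records.append(rec)
        prev = fit
    fitted = [r for r in trace.records if not r["failed"]]
    trace.chosen_n = int(min(fitted, key=lambda r: r["aic"])["n_phases"])
    return trace


def normal_ci(point: float, se: float, level: float = 0.95) -> tuple:
    """Normal-approximation interval ``point +/- z * se`` (z = 1.96 at 95%)."""
    z = stats.norm.ppf(0.5 + level / 2)
    return (point - z * se, point + z * se)


def bootstrap_inference(
    sample: SurvivalSample,
    effects,
    fit: RegressionFitResult,
    B: int = 500,
    seed: int = 0,
    maxfev: int = 2000,
) -> BootstrapSummary:
    """Nonparametric subject-level bootstrap of the factors ``e^{-alpha}``.

    Subjects are resampled with replacement; each replicate is refitted by a
    single Nelder-Mead run warm-started at the full-data optimum.  The SE is
    the standard deviation of the replicate factors and the reported CI is
    the normal approximation ``point +/- 1.96 se``; percentile intervals are
    stored alongside.  Non-converged replicates are dropped and counted;
    more than 20% dropped flags a warning status.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    X = _scale_covariates(sample, effects)
    times, events = sample.times, sample.events
    n = fit.baseline.n_phases
    z0 = np.concatenate([_pack_rates(fit.baseline), fit.coefficients.as_array])
    rng = np.random.default_rng(seed)
    M = sample.n
    rows = []
    n_dropped = 0
    for b in range(B):
        idx = rng.integers(0, M, size=M)
        tb, eb, Xb = times[idx], events[idx], X[idx]

        def objective(z):
            x, alpha = z[: 2 * n - 1], z[2 * n - 1 :]
            if np.any(x > 15) or np.any(x < -40) or np.any(np.abs(alpha) > 50):
                return _PENALTY
            lams, mus = _unpack_rates(x, n)
            ll = _regression_loglik_arrays(lams, mus, alpha, tb, eb, Xb)
            return -ll if np.isfinite(ll) else _PENALTY

        # Warm-started and only feeding a spread estimate, so a coarse
        # tolerance suffices.
        res = optimize.minimize(
            objective, z0, method="Nelder-Mead",
            options={"fatol": 1e-4, "xatol": 1e-3, "maxfev": maxfev},
        )
        if not np.isfinite(res.fun) or res.fun >= _PENALTY:
            n_dropped += 1
            continue
        alpha_b = res.x[2 * n - 1 :]
        rows.append(
            {
                "replicate": b,
                "alpha1": float(alpha_b[0]),
                "alpha2": float(alpha_b[1]),
                "exp_alpha1": float(np.exp(-alpha_b[0])),
                "exp_alpha2": float(np.exp(-alpha_b[1])),
                "converged": bool(res.success),
            }
        )
    reps = pd.DataFrame(rows)
    if len(reps) < 2:
        raise ConvergenceError("fewer than two bootstrap replicates converged")
    point1 = float(np.exp(-fit.coefficients.alpha1))
    point2 = float(np.exp(-fit.coefficients.alpha2))
    se1 = float(reps["exp_alpha1"].std(ddof=1))
    se2 = float(reps["exp_alpha2"].std(ddof=1))
    pctl = lambda col: tuple(np.percentile(reps[col], [2.5, 97.5]))
    status = "ok" if n_dropped <= 0.2 * B else "warning: >20% replicates dropped"
    return BootstrapSummary(
        B=B,
        point_exp_alpha1=point1,
        point_exp_alpha2=point2,
        se_exp_alpha1=se1,
        se_exp_alpha2=se2,
        ci_exp_alpha1=normal_ci(point1, se1),
        ci_exp_alpha2=normal_ci(point2, se2),
        percentile_ci_exp_alpha1=pctl("exp_alpha1"),
        percentile_ci_exp_alpha2=pctl("exp_alpha2"),
        replicate_estimates=reps,
        n_dropped=n_dropped,
        status=status,
        seed=seed,
    )


def significance_from_ci(summary: BootstrapSummary) -> dict:
    """A factor is significant iff 1 lies outside its closed 95% CI."""

    def sig(ci):
        lo, hi = ci
        return not (lo <= 1.0 <= hi)

    return {
        "alpha1": sig(summary.ci_exp_alpha1),
        "alpha2": sig(summary.ci_exp_alpha2),
    }


def _factors(fit, effects, t, scaling_time):
    coeffs = fit.coefficients
    if scaling_time is None:
        return rate_scaling_factor(effects, t, coeffs)
    return rate_scaling_factor(effects, float(scaling_time), coeffs)


def individual_survivor(
    fit: RegressionFitResult, effects: SubjectRandomEffects, t, scaling_time=None
):
    """Subject-specific survival probability.

    Because a uniformly scaled generator is a time change,
    ``S_i(t) = S0(c t)`` where ``c`` is the subject's rate-of-flow factor.
    With ``scaling_time=None`` the factor is re-evaluated at each requested
    ``t`` (literal time-varying exponent); passing ``scaling_time=tau``
    freezes the factor at the subject's biomarker observation time ``tau``,
    the convention used for personalised survival curves.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    c = np.atleast_1d(_factors(fit, effects, t_arr, scaling_time))
    S = survivor(fit.baseline, c * t_arr)
    S = np.atleast_1d(S)
    return float(S[0]) if np.ndim(t) == 0 else S


def individual_hazard(
    fit: RegressionFitResult, effects: SubjectRandomEffects, t, scaling_time=None
):
    """Subject-specific hazard ``h_i(t) = c * h0(c t)``; converges to the
    personalised final-phase rate ``c * mu_n`` (frozen-factor mode)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    c = np.atleast_1d(_factors(fit, effects, t_arr, scaling_time))
    h = np.atleast_1d(hazard(fit.baseline, c * t_arr)) * c
    return float(h[0]) if np.ndim(t) == 0 else h
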