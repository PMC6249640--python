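"""Maximum-likelihood fitting of the Coxian phase-type distribution.

The log-likelihood sums ``log f(t_i)`` over observed events and ``log
S(t_i)`` over right-censored subjects.  Because the fit is strongly
influenced by the starting values, optimisation is multi-start Nelder-Mead
over the ``2n - 1`` free log-rates (positivity by construction, ``lambda_n``
pinned at zero), with starts scaled to the sample mean time.  The number of
phases is chosen by sequentially increasing ``n`` and stopping when a
likelihood-ratio test against ``n - 1`` phases is non-significant and the
AIC no longer improves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import CoxianParameters, _density_survivor_arrays

#: log-rate floor standing in for an exactly-zero rate.
LOG_RATE_FLOOR = -30.0

#: Log-density floor guarding -inf contributions during the search.
_LOG_FLOOR = 1e-300

_PENALTY = 1e10

__all__ = [
    "SurvivalSample",
    "FitResult",
    "ModelSelectionTrace",
    "ConvergenceError",
    "loglikelihood",
    "fit_coxian",
    "select_phases",
]


@dataclass(frozen=True)
class SurvivalSample:
    """Per-subject event/censoring times (months) with event indicators."""

    subject_ids: np.ndarray
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.subject_ids)
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=int)
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        if not (ids.size == times.size == events.size):
            raise ValueError("subject_ids, times and events must have equal length")
        if ids.size == 0:
            raise ValueError("sample is empty")
        if pd.Index(ids).has_duplicates:
            raise ValueError("subject ids must be unique")
        if np.any(times <= 0):
            raise ValueError("all times must be positive")
        if not np.all(np.isin(events, (0, 1))):
            raise ValueError("events must be 0 (censored) or 1 (event)")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalSample":
        return cls(
            subject_ids=df["id"].to_numpy(),
            times=df["time"].to_numpy(dtype=float),
            events=df["event"].to_numpy(dtype=int),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.subject_ids, "time": self.times, "event": self.events}
        )


@dataclass(frozen=True)
class FitResult:
    """Best-of-restarts maximum-likelihood fit of an ``n``-phase Coxian."""

    params: CoxianParameters
    loglik: float
    aic: float
    bic: float
    n_restarts: int
    best_start_index: int
    converged: bool
    seed: int

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_config(),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_restarts": self.n_restarts,
            "best_start_index": self.best_start_index,
            "converged": self.converged,
            "seed": self.seed,
        }


@dataclass
class ModelSelectionTrace:
    """Per-``n`` fits with LRT statistics against ``n - 1`` phases."""

    records: list = field(default_factory=list)
    chosen_n: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _loglik_terms(lambdas, mus, times, events):
    f, S = _density_survivor_arrays(lambdas, mus, times)
    out = np.where(
        events == 1, np.log(np.maximum(f, _LOG_FLOOR)), np.log(np.maximum(S, _LOG_FLOOR))
    )
    return float(out.sum())


def loglikelihood(params: CoxianParameters, sample: SurvivalSample) -> float:
    """Log-likelihood: density terms for events, survivor terms for
    right-censored subjects; log-floored rather than ``-inf``."""
    return _loglik_terms(params.lambdas, params.mus, sample.times, sample.events)


def _unpack_rates(x: np.ndarray, n: int):
    """Free vector -> (lambdas, mus): x = [log lam_1..lam_{n-1}, log mu_1..mu_n]."""
    lams = np.zeros(n)
    if n > 1:
        lams[: n - 1] = np.exp(x[: n - 1])
    mus = np.exp(x[n - 1 :])
    return lams, mus


def _pack_rates(params: CoxianParameters) -> np.ndarray:
    n = params.n_phases
    x = np.empty(2 * n - 1)
    x[: n - 1] = np.log(np.maximum(params.lambdas[:-1], np.exp(LOG_RATE_FLOOR)))
    x[n - 1 :] = np.log(np.maximum(params.mus, np.exp(LOG_RATE_FLOOR)))
    return x


class ConvergenceError(RuntimeError):
    """No restart converged; carries the best partial result if any."""

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


def _multistart(objective, starts, maxfev=20000):
    """Run Nelder-Mead from each start; returns (best_x, best_f, index, ok)."""
    best_x, best_f, best_i, best_ok = None, np.inf, -1, False
    for i, x0 in enumerate(starts):
        # Coarse tolerance per restart; only the winner is polished tightly.
        res = optimize.minimize(
            objective,
            np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            options={"fatol": 1e-5, "xatol": 1e-4, "maxfev": maxfev},
        )
        if res.fun < best_f:
            best_x, best_f, best_i, best_ok = res.x, res.fun, i, bool(res.success)
    if best_x is None or best_f >= _PENALTY:
        raise ConvergenceError("no restart reached a valid parameter region")
    # Polish the winner with tighter tolerances.
    res = optimize.minimize(
        objective,
        best_x,
        method="Nelder-Mead",
        options={"fatol": 1e-12, "xatol": 1e-9, "maxfev": maxfev},
    )
    if res.fun <= best_f:
        best_x, best_f = res.x, res.fun
        best_ok = best_ok or bool(res.success)
    return best_x, best_f, best_i, best_ok


def _random_starts(rng, n_restarts, dim, mean_time):
    lo, hi = np.log(0.1 / mean_time), np.log(10.0 / mean_time)
    return rng.uniform(lo, hi, size=(n_restarts, dim))


def fit_coxian(
    sample: SurvivalSample,
    n_phases: int,
    n_restarts: int = 50,
    seed: int = 0,
    extra_starts=None,
) -> FitResult:
    """Best-of-restarts MLE of an ``n``-phase Coxian.

    Starts are drawn log-uniformly on ``[0.1/tbar, 10/tbar]`` where ``tbar``
    is the mean observed time, scaling the search to the data;
    ``extra_starts`` (parameter vectors) seed additional deterministic
    restarts, used by phase selection to enforce likelihood nesting.
    Deterministic given ``seed``.
    """
    if n_phases < 1:
        raise ValueError("n_phases must be at least 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be at least 1")
    n = n_phases
    times, events = sample.times, sample.events

    def objective(x):
        if np.any(x > 15) or np.any(x < -40):
            return _PENALTY
        lams, mus = _unpack_rates(x, n)
        ll = _loglik_terms(lams, mus, times, events)
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    rng = np.random.default_rng(seed)
    starts = list(_random_starts(rng, n_restarts, 2 * n - 1, times.mean()))
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    x, negll, idx, ok = _multistart(objective, starts)
    lams, mus = _unpack_rates(x, n)
    params = CoxianParameters(lams, mus)
    ll = -negll
    k = 2 * n - 1
    M = sample.n
    return FitResult(
        params=params,
        loglik=ll,
        aic=-2 * ll + 2 * k,
        bic=-2 * ll + k * np.log(M),
        n_restarts=len(starts),
        best_start_index=idx,
        converged=ok,
        seed=seed,
    )


def _padded_start(fit: FitResult) -> np.ndarray:
    """Start vector for ``n + 1`` phases from an ``n``-phase solution.

    The extra phase is appended with a tiny absorption rate and the old
    final phase is given a tiny onward rate, leaving the likelihood
    essentially unchanged -- this enforces nesting of the optima.
    """
    n = fit.params.n_phases
    lams = np.concatenate([fit.params.lambdas[:-1], [np.exp(LOG_RATE_FLOOR)], [0.0]])
    mus = np.concatenate([fit.params.mus, [fit.params.mus[-1]]])
    return _pack_rates(CoxianParameters(lams, mus))


def select_phases(
    sample: SurvivalSample,
    max_phases: int,
    alpha_level: float = 0.05,
    n_restarts: int = 50,
    seed: int = 0,
) -> ModelSelectionTrace:
    """Sequentially fit ``n = 1..max_phases``; stop when the 2-df LRT versus
    ``n - 1`` phases is non-significant *and* the AIC worsens.

    The chi-square(2) reference follows standard practice for the two extra
    rates, acknowledging the boundary non-regularity of rates at zero.  The
    full trace (loglik, AIC, BIC, LRT) is recorded; ``chosen_n`` is the last
    ``n`` before the stop, or the AIC minimiser if no stop is triggered.
    """
    if max_phases < 2:
        raise ValueError("max_phases must be at least 2")
    trace = ModelSelectionTrace()
    prev: FitResult | None = None
    for n in range(1, max_phases + 1):
        extra = [_padded_start(prev)] if prev is not None else None
        try:
            fit = fit_coxian(
                sample, n, n_restarts=n_restarts, seed=seed + n, extra_starts=extra
            )
        except RuntimeError as err:
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
            pval = float(stats.chi2.sf(stat, df=2))
            rec["lrt_stat"] = stat
            rec["lrt_p"] = pval
            if pval > alpha_level and fit.aic > prev.aic:
                trace.records.append(rec)
                trace.chosen_n = prev.params.n_phases
                return trace
        trace.records.append(rec)
        prev = fit
    fitted = [r for r in trace.records if not r["failed"]]
    trace.chosen_n = int(min(fitted, key=lambda r: r["aic"])["n_phases"])
    return trace
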