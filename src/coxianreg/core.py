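"""Exact mathematics of the Coxian phase-type distribution.

A Coxian phase-type distribution describes the time to absorption of a
continuous-time Markov chain with ``n`` ordered transient phases.  From phase
``k`` an individual either moves onward to phase ``k+1`` at rate ``lambda_k``
(per month) or is absorbed -- experiences the event of interest -- at rate
``mu_k``.  Everyone starts in phase 1 and ``lambda_n = 0``, so the final phase
can only absorb.  The free parameter count is ``2n - 1``.

This module provides the generator-matrix representation, the density in both
its matrix-exponential and analytic (partial-fraction) forms, survivor /
hazard / cumulative-hazard functions, per-phase absorption probabilities, the
partition of ordered event times into phase cohorts, trajectory sampling, and
a canonical re-parameterisation used when comparing fitted rate vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, solve_triangular

logger = logging.getLogger(__name__)

#: Relative gap below which two total rates are treated as tied, making the
#: partial-fraction expansion ill-defined.
DEGENERACY_RTOL = 1e-9

#: Survivor values below this are treated as underflowed.
SURVIVOR_FLOOR = 1e-300

__all__ = [
    "CoxianParameters",
    "GeneratorSystem",
    "AbsorptionProfile",
    "PhasePartition",
    "CoxianValidationError",
    "DegenerateRatesError",
    "build_generator",
    "pdf_matrix",
    "pdf_analytic",
    "pdf",
    "survivor",
    "hazard",
    "cumulative_hazard",
    "absorption_probabilities",
    "phase_time_bounds",
    "sample_absorption_times",
    "canonical_form",
]


class CoxianValidationError(ValueError):
    """Raised when a rate specification violates the Coxian structure."""


class DegenerateRatesError(ValueError):
    """Raised when tied total rates make the analytic expansion undefined."""


@dataclass(frozen=True)
class CoxianParameters:
    """Sequential transition rates ``lambda_k`` and absorption rates ``mu_k``.

    Rates are per month.  ``lambdas[-1]`` must be exactly 0 and ``mus[-1]``
    strictly positive; every transient phase must have positive total
    outflow so the chain cannot be trapped.
    """

    lambdas: np.ndarray
    mus: np.ndarray

    def __post_init__(self) -> None:
        lams = np.asarray(self.lambdas, dtype=float)
        mus = np.asarray(self.mus, dtype=float)
        object.__setattr__(self, "lambdas", lams)
        object.__setattr__(self, "mus", mus)
        if lams.ndim != 1 or mus.ndim != 1:
            raise CoxianValidationError("lambdas and mus must be 1-d sequences")
        if lams.size != mus.size:
            raise CoxianValidationError(
                f"length mismatch: {lams.size} lambdas vs {mus.size} mus"
            )
        if lams.size < 1:
            raise CoxianValidationError("at least one phase is required")
        if not (np.all(np.isfinite(lams)) and np.all(np.isfinite(mus))):
            raise CoxianValidationError("rates must be finite")
        for k, lam in enumerate(lams, start=1):
            if lam < 0:
                raise CoxianValidationError(f"lambda_{k} = {lam} is negative")
        for k, mu in enumerate(mus, start=1):
            if mu < 0:
                raise CoxianValidationError(f"mu_{k} = {mu} is negative")
        n = lams.size
        if lams[-1] != 0.0:
            raise CoxianValidationError(
                f"lambda_{n} = {lams[-1]} must be exactly 0 (final phase)"
            )
        if mus[-1] <= 0.0:
            raise CoxianValidationError(
                f"mu_{n} = {mus[-1]} must be positive (final phase must absorb)"
            )
        totals = lams + mus
        for k in range(n - 1):
            if totals[k] <= 0.0:
                raise CoxianValidationError(
                    f"phase {k + 1} has zero total outflow (trapping state)"
                )

    @property
    def n_phases(self) -> int:
        return int(self.lambdas.size)

    @property
    def total_rates(self) -> np.ndarray:
        """Total outflow rate ``sigma_k = lambda_k + mu_k`` of each phase."""
        return self.lambdas + self.mus

    def scaled(self, factor: float) -> "CoxianParameters":
        """All rates multiplied by a common positive factor."""
        if not np.isfinite(factor) or factor <= 0:
            raise ValueError(f"scaling factor must be positive, got {factor}")
        return CoxianParameters(self.lambdas * factor, self.mus * factor)

    def to_config(self) -> dict:
        """Flat key-value serialisation (n, lambda_1.., mu_1..)."""
        cfg = {"n": self.n_phases}
        for k in range(self.n_phases):
            cfg[f"lambda_{k + 1}"] = float(self.lambdas[k])
            cfg[f"mu_{k + 1}"] = float(self.mus[k])
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "CoxianParameters":
        n = int(cfg["n"])
        lams = [float(cfg[f"lambda_{k + 1}"]) for k in range(n)]
        mus = [float(cfg[f"mu_{k + 1}"]) for k in range(n)]
        return cls(np.array(lams), np.array(mus))


@dataclass(frozen=True)
class GeneratorSystem:
    """Transient-phase generator ``Q``, initial row ``p`` and absorption
    column ``q`` of the Markov system: ``f(t) = p expm(Qt) q``."""

    Q: np.ndarray
    p: np.ndarray
    q: np.ndarray


@dataclass(frozen=True)
class AbsorptionProfile:
    """Probabilities ``pi_k`` of experiencing the event from each phase."""

    pis: np.ndarray

    def __post_init__(self) -> None:
        pis = np.asarray(self.pis, dtype=float)
        object.__setattr__(self, "pis", pis)
        if np.any(pis < -1e-12) or np.any(pis > 1 + 1e-12):
            raise CoxianValidationError("absorption probabilities outside [0, 1]")
        if abs(pis.sum() - 1.0) > 1e-9:
            raise CoxianValidationError(
                f"absorption probabilities sum to {pis.sum()}, not 1"
            )


@dataclass(frozen=True)
class PhasePartition:
    """Partition of the ordered event times into per-phase blocks.

    ``bounds[g]`` is the half-open index interval ``(lower, upper]`` (1-based
    ranks) of the ordered times attributed to phase ``g + 1``;
    ``assignments[j]`` is the phase label (1-based) of the ``j``-th ordered
    time.
    """

    bounds: tuple
    assignments: np.ndarray = field(repr=False)


def build_generator(params: CoxianParameters) -> GeneratorSystem:
    """Bidiagonal generator matrix of the transient phases.

    Row ``k`` has diagonal ``-(lambda_k + mu_k)`` and superdiagonal
    ``lambda_k``; row sums equal ``-mu_k``, the rate of leaving the transient
    block.  The initial distribution puts all mass on phase 1.
    """
    n = params.n_phases
    Q = np.zeros((n, n))
    np.fill_diagonal(Q, -(params.lambdas + params.mus))
    if n > 1:
        Q[np.arange(n - 1), np.arange(1, n)] = params.lambdas[:-1]
    p = np.zeros(n)
    p[0] = 1.0
    return GeneratorSystem(Q=Q, p=p, q=params.mus.copy())


def _check_times(t) -> np.ndarray:
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    return t_arr


def _as_output(values: np.ndarray, t) -> "float | np.ndarray":
    return float(values[0]) if np.isscalar(t) or np.ndim(t) == 0 else values


def _mixture_coefficients(lambdas: np.ndarray, mus: np.ndarray):
    """Partial-fraction representation of the density.

    Returns ``(sigma, a)`` with ``f(t) = sum_k a_k sigma_k e^{-sigma_k t}``
    and ``S(t) = sum_k a_k e^{-sigma_k t}``, where ``sigma_k`` are the total
    phase outflow rates.  ``a_k = sum_{h>=k} pi_h C_kh`` collects, over every
    exit phase ``h`` reachable after ``k``, the exit probability ``pi_h``
    times the hypoexponential partial-fraction coefficient ``C_kh``.

    Raises
    ------
    DegenerateRatesError
        If two total rates are tied within ``DEGENERACY_RTOL`` relative.
    """
    sigma = lambdas + mus
    n = sigma.size
    if n > 1:
        pair_scale = np.maximum(sigma[:, None], sigma[None, :])
        rel = np.abs(sigma[:, None] - sigma[None, :]) / pair_scale
        np.fill_diagonal(rel, np.inf)
        if rel.min() <= DEGENERACY_RTOL:
            i, j = divmod(int(rel.argmin()), n)
            raise DegenerateRatesError(
                f"total rates of phases {i + 1} and {j + 1} are tied "
                f"({sigma[i]} vs {sigma[j]}); analytic form undefined"
            )
    pis = _exit_probabilities(lambdas, mus)
    a = np.zeros(n)
    for h in range(n):  # exit phase (0-based)
        if pis[h] == 0.0:
            continue
        sub = sigma[: h + 1]
        for k in range(h + 1):
            others = np.delete(sub, k)
            c_kh = np.prod(others / (others - sub[k]))
            a[k] += pis[h] * c_kh
    return sigma, a


def _exit_probabilities(lambdas: np.ndarray, mus: np.ndarray) -> np.ndarray:
    sigma = lambdas + mus
    reach = np.concatenate(([1.0], np.cumprod(lambdas[:-1] / sigma[:-1])))
    return reach * mus / sigma


def _density_survivor_arrays(
    lambdas: np.ndarray, mus: np.ndarray, t: np.ndarray
):
    """Vectorised density and survivor with matrix-exponential fallback.

    The analytic partial-fraction form is used whenever the total rates are
    well separated; points where cancellation drives the result out of range
    (negative density, survivor outside [0, 1]) are recomputed with the
    matrix exponential.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    try:
        sigma, a = _mixture_coefficients(lambdas, mus)
    except DegenerateRatesError:
        return _density_survivor_matrix(lambdas, mus, t)
    E = np.exp(-np.outer(sigma, t))
    f = (a * sigma) @ E
    S = a @ E
    bad = ~np.isfinite(f) | ~np.isfinite(S) | (f < 0) | (S < 0) | (S > 1 + 1e-9)
    if np.any(bad):
        fb, Sb = _density_survivor_matrix(lambdas, mus, t[bad])
        f = f.copy()
        S = S.copy()
        f[bad] = fb
        S[bad] = Sb
    return f, np.clip(S, 0.0, 1.0)


def _density_survivor_matrix(lambdas: np.ndarray, mus: np.ndarray, t: np.ndarray):
    params = CoxianParameters(lambdas, mus)
    gen = build_generator(params)
    f = np.empty(t.size)
    S = np.empty(t.size)
    for i, ti in enumerate(np.asarray(t, dtype=float)):
        row = gen.p @ expm(gen.Q * ti)
        f[i] = max(row @ gen.q, 0.0)
        S[i] = min(max(row.sum(), 0.0), 1.0)
    return f, S


def pdf_matrix(params: CoxianParameters, t) -> "float | np.ndarray":
    """Density ``f(t) = p expm(Qt) q`` via the matrix exponential.

    Numerically robust for any valid parameters (scaling-and-squaring Pade
    approximation); the reference form against which the analytic expansion
    is validated.
    """
    t_arr = np.atleast_1d(_check_times(t))
    f, _ = _density_survivor_matrix(params.lambdas, params.mus, t_arr)
    return _as_output(f, t)


def pdf_analytic(params: CoxianParameters, t) -> "float | np.ndarray":
    """Analytic density: a signed mixture of exponentials.

    ``f(t) = sum_h pi_h sum_{k<=h} C_kh sigma_k e^{-sigma_k t}`` where
    ``sigma_k`` is phase ``k``'s total outflow rate, ``pi_h`` the exit
    probability from phase ``h`` and ``C_kh`` the hypoexponential
    partial-fraction coefficients.  Requires pairwise-distinct total rates.

    Raises
    ------
    DegenerateRatesError
        If two total rates coincide; callers fall back to :func:`pdf_matrix`.
    """
    t_arr = np.atleast_1d(_check_times(t))
    sigma, a = _mixture_coefficients(params.lambdas, params.mus)
    f = (a * sigma) @ np.exp(-np.outer(sigma, t_arr))
    return _as_output(f, t)


def pdf(params: CoxianParameters, t, method: str = "auto") -> "float | np.ndarray":
    """Density with automatic analytic/matrix dispatch."""
    if method == "matrix":
        return pdf_matrix(params, t)
    if method == "analytic":
        return pdf_analytic(params, t)
    t_arr = np.atleast_1d(_check_times(t))
    f, _ = _density_survivor_arrays(params.lambdas, params.mus, t_arr)
    return _as_output(f, t)


def survivor(params: CoxianParameters, t, method: str = "auto") -> "float | np.ndarray":
    """Survivor function ``S(t) = p expm(Qt) 1``.

    Monotone non-increasing with ``S(0) = 1``.  The analytic fast path
    ``S(t) = sum_k a_k e^{-sigma_k t}`` (term-wise integral of the analytic
    density) is used when the total rates are distinct.
    """
    t_arr = np.atleast_1d(_check_times(t))
    if method == "matrix":
        _, S = _density_survivor_matrix(params.lambdas, params.mus, t_arr)
    else:
        _, S = _density_survivor_arrays(params.lambdas, params.mus, t_arr)
    return _as_output(S, t)


def hazard(params: CoxianParameters, t) -> "float | np.ndarray":
    """Hazard ``h(t) = f(t) / S(t)``.

    A convex combination of the per-phase absorption rates weighted by the
    probability of occupying each phase given survival, hence bounded between
    ``min(mu_k)`` and ``max(mu_k)``.  Where the survivor has underflowed the
    final-phase rate ``mu_n`` (the limiting hazard when the final phase is
    the slowest) is returned.
    """
    t_arr = np.atleast_1d(_check_times(t))
    f, S = _density_survivor_arrays(params.lambdas, params.mus, t_arr)
    under = S < SURVIVOR_FLOOR
    if np.any(under):
        logger.debug(
            "survivor underflow at %d time point(s); returning limiting hazard mu_n",
            int(under.sum()),
        )
    h = np.empty(t_arr.size)
    h[~under] = f[~under] / S[~under]
    h[under] = params.mus[-1]
    return _as_output(h, t)


def cumulative_hazard(params: CoxianParameters, t) -> "float | np.ndarray":
    """Cumulative hazard ``H(t) = -log S(t)``; non-decreasing, ``H(0) = 0``.

    Beyond survivor underflow the exact asymptote of ``-log S`` is used:
    linear with the slowest mode's rate ``sigma_min`` and its amplitude.
    """
    t_arr = np.atleast_1d(_check_times(t))
    _, S = _density_survivor_arrays(params.lambdas, params.mus, t_arr)
    under = S < SURVIVOR_FLOOR
    H = np.empty(t_arr.size)
    H[~under] = -np.log(S[~under])
    if np.any(under):
        try:
            sigma, a = _mixture_coefficients(params.lambdas, params.mus)
            k = int(np.argmin(sigma))
            amp = np.log(a[k]) if a[k] > 0 else 0.0
        except DegenerateRatesError:
            sigma = params.total_rates
            k = int(np.argmin(sigma))
            amp = 0.0
        H[under] = sigma[k] * t_arr[under] - amp
    return _as_output(H, t)


def absorption_probabilities(params: CoxianParameters) -> AbsorptionProfile:
    """Probability ``pi_k`` of exiting the system from each phase.

    ``pi_k = (mu_k / sigma_k) * prod_{j<k} (lambda_j / sigma_j)``: survive
    sequentially to phase ``k`` and then absorb.  Sums to 1 because
    ``lambda_n = 0`` closes the chain.
    """
    pis = _exit_probabilities(params.lambdas, params.mus)
    return AbsorptionProfile(pis=pis)


def phase_time_bounds(profile: AbsorptionProfile, ordered_times) -> PhasePartition:
    """Partition ordered event times into phase cohorts in ratio pi_1:..:pi_n.

    The cumulative cut for phase ``g`` is ``floor(M * sum_{k<=g} pi_k)``; the
    final cut is forced to ``M`` so the blocks are contiguous, disjoint and
    exhaustive.  Expected blocks smaller than one observation may be empty.
    """
    times = np.asarray(ordered_times, dtype=float)
    if times.size == 0:
        raise CoxianValidationError("ordered_times must be non-empty")
    if np.any(np.diff(times) < 0):
        raise CoxianValidationError("ordered_times must be sorted ascending")
    M = times.size
    cuts = np.floor(M * np.cumsum(profile.pis)).astype(int)
    cuts = np.maximum.accumulate(cuts)
    cuts[-1] = M
    lowers = np.concatenate(([0], cuts[:-1]))
    bounds = tuple((int(lo), int(hi)) for lo, hi in zip(lowers, cuts))
    assignments = np.repeat(
        np.arange(1, len(bounds) + 1), cuts - lowers
    )
    return PhasePartition(bounds=bounds, assignments=assignments)


def _sample_paths(params: CoxianParameters, m: int, rng: np.random.Generator):
    """Simulate ``m`` trajectories; returns (absorption times, exit phases).

    In phase ``k`` the dwell is exponential with rate ``sigma_k`` and the
    exit is to absorption with probability ``mu_k / sigma_k``.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    sigma = params.total_rates
    times = np.zeros(m)
    exit_phase = np.zeros(m, dtype=int)
    active = np.arange(m)
    for k in range(params.n_phases):
        if active.size == 0:
            break
        times[active] += rng.exponential(1.0 / sigma[k], size=active.size)
        absorb = rng.random(active.size) * sigma[k] < params.mus[k]
        exit_phase[active[absorb]] = k + 1
        active = active[~absorb]
    return times, exit_phase


def sample_absorption_times(
    params: CoxianParameters, m: int, seed: "int | np.random.Generator"
) -> np.ndarray:
    """Draw ``m`` absorption times by phase-wise competing-exponential
    simulation; reproducible per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times, _ = _sample_paths(params, m, rng)
    return times


def canonical_form(params: CoxianParameters) -> CoxianParameters:
    """Equivalent Coxian with total rates sorted in decreasing order.

    The density of a Coxian determines its exponential modes (poles) and
    their weights but not the phase labelling, so distinct rate vectors can
    share one distribution.  This re-solves the exit probabilities against
    the hypoexponential basis taken in decreasing-rate order and rebuilds
    ``(lambda, mu)``, giving a unique representative for rate comparisons.
    """
    sigma, a = _mixture_coefficients(params.lambdas, params.mus)
    n = sigma.size
    order = np.argsort(-sigma, kind="stable")
    s = sigma[order]
    c = (a * sigma)[order]  # density coefficient attached to each pole
    # Basis matrix: column h holds the pole coefficients of the
    # hypoexponential through phases 1..h+1 in the new ordering.
    B = np.zeros((n, n))
    for h in range(n):
        sub = s[: h + 1]
        for k in range(h + 1):
            others = np.delete(sub, k)
            B[k, h] = np.prod(others / (others - sub[k])) * sub[k]
    pis = solve_triangular(B, c, lower=False)
    pis = np.clip(pis, 0.0, None)
    pis = pis / pis.sum()
    # Rebuild rates from exit probabilities along the ordered chain.
    mus = np.empty(n)
    lams = np.empty(n)
    reach = 1.0
    for h in range(n):
        exit_prob = 1.0 if h == n - 1 else min(pis[h] / reach, 1.0) if reach > 0 else 1.0
        mus[h] = s[h] * exit_prob
        lams[h] = s[h] - mus[h]
        reach *= 1.0 - exit_prob
    lams[-1] = 0.0
    lams = np.clip(lams, 0.0, None)
    return CoxianParameters(lams, mus)
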