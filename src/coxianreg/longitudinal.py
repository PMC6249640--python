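"""Stage 1: linear mixed effects model with random intercept and slope.

The longitudinal biomarker (e.g. haemoglobin in g/dL) is modelled as
``y_ij = x_ij' beta + b_i0 + b_i1 t_ij + e_ij`` with subject random effects
``b_i ~ N(0, D)`` (2x2 covariance) and independent Gaussian residuals of
variance ``sigma2``.  Estimation delegates to statsmodels' MixedLM (ML by
default, REML optional); per-subject random effects are then predicted by
the empirical BLUP ``b_i = D Z_i' V_i^{-1} (y_i - X_i beta)`` with
``V_i = Z_i D Z_i' + sigma2 I``, and feed Stage 2 as covariates.

Continuous fixed covariates (other than time) are centred about their
sample means; the centring constants are stored so Stage-2 inputs are
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "LMEEstimates",
    "validate_longitudinal",
    "fit_lme",
    "predict_random_effects",
    "lrt_random_effects",
]

REQUIRED_COLUMNS = ("id", "time", "response")


@dataclass(frozen=True)
class LMEEstimates:
    """ML/REML estimates of the mixed model.

    ``beta`` is indexed by design column ("intercept", "time", covariates);
    ``D`` is the 2x2 random intercept/slope covariance (natural units);
    ``sigma2`` the residual variance.  ``n_re`` records how many random
    effects were fitted (2 = intercept+slope, 1 = intercept, 0 = none).
    """

    beta: pd.Series
    D: np.ndarray
    sigma2: float
    loglik: float
    n_re: int
    fixed_effects: tuple
    centering: dict = field(default_factory=dict)
    reml: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        object.__setattr__(self, "D", D)
        if D.shape != (2, 2):
            raise ValueError("D must be 2x2 (intercept, slope)")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("D must be symmetric")
        if np.min(np.linalg.eigvalsh(D)) < -1e-8:
            raise ValueError("D must be positive semi-definite")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "D": self.D.tolist(),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "n_re": self.n_re,
            "fixed_effects": list(self.fixed_effects),
            "centering": self.centering,
            "reml": self.reml,
            "converged": self.converged,
        }


def validate_longitudinal(data: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format table: required columns, nonnegative times, no
    missing responses, and slope identifiability (some subject with >= 2
    observations)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"longitudinal table missing columns: {missing}")
    if data["response"].isna().any():
        bad = data.index[data["response"].isna()].tolist()[:5]
        raise ValueError(f"missing response values at rows {bad}")
    if (data["time"] < 0).any():
        bad = data.index[data["time"] < 0].tolist()[:5]
        raise ValueError(f"negative observation times at rows {bad}")
    if not (data.groupby("id").size() >= 2).any():
        raise ValueError("no subject has >= 2 observations; slope unidentifiable")
    return data


def _design(data: pd.DataFrame, fixed_effects, centering) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X["intercept"] = 1.0
    X["time"] = data["time"].astype(float)
    for col in fixed_effects:
        if col not in data.columns:
            raise ValueError(f"fixed-effect column '{col}' not in data")
        X[col] = data[col].astype(float) - centering.get(col, 0.0)
    return X


def _centering_constants(data: pd.DataFrame, fixed_effects) -> dict:
    """Means of continuous covariates (binary/dummy columns are left
    uncentred, time is never centred)."""
    centering = {}
    for col in fixed_effects:
        if col not in data.columns:
            raise ValueError(f"fixed-effect column '{col}' not in data")
        vals = data[col]
        if vals.nunique() > 2:
            centering[col] = float(vals.mean())
    return centering


def fit_lme(
    data: pd.DataFrame,
    fixed_effects=(),
    reml: bool = False,
    random_effects: str = "intercept_slope",
) -> LMEEstimates:
    """Fit the mixed model (default ML so fixed-effect LRTs remain valid).

    ``random_effects`` selects the nested structure used by the LRTs:
    "intercept_slope" (default), "intercept", or "none" (plain OLS).
    """
    data = validate_longitudinal(data)
    fixed_effects = tuple(fixed_effects)
    centering = _centering_constants(data, fixed_effects)
    X = _design(data, fixed_effects, centering)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"singular fixed-effect design; columns {list(X.columns)}")
    y = data["response"].astype(float)

    if random_effects == "none":
        res = sm.OLS(y, X).fit()
        D = np.zeros((2, 2))
        return LMEEstimates(
            beta=res.params, D=D, sigma2=float(res.scale), loglik=float(res.llf),
            n_re=0, fixed_effects=fixed_effects, centering=centering, reml=reml,
        )
    if random_effects == "intercept":
        exog_re = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    elif random_effects == "intercept_slope":
        exog_re = X[["intercept", "time"]]
    else:
        raise ValueError(f"unknown random_effects spec '{random_effects}'")

    model = sm.MixedLM(y, X, groups=data["id"], exog_re=exog_re)
    res = None
    for method in (None, "lbfgs", "powell"):
        kwargs = {"reml": reml}
        if method is not None:
            kwargs["method"] = method
        try:
            with warnings.catch_warnings():
                # convergence is checked explicitly below, with retries
                warnings.simplefilter("ignore")
                candidate = model.fit(**kwargs)
        except np.linalg.LinAlgError:
            continue
        if candidate.converged:
            res = candidate
            break
        res = res or candidate
    if res is None or not res.converged:
        raise RuntimeError(
            "mixed-model optimisation did not converge"
            + (f"; final log-likelihood {res.llf}" if res is not None else "")
        )
    cov_re = np.asarray(res.cov_re)
    D = np.zeros((2, 2))
    if random_effects == "intercept":
        D[0, 0] = cov_re[0, 0]
    else:
        D[:, :] = cov_re
    # Guard tiny asymmetries / negative eigenvalues from the optimiser.
    D = (D + D.T) / 2
    w, V = np.linalg.eigh(D)
    D = (V * np.clip(w, 0.0, None)) @ V.T
    return LMEEstimates(
        beta=res.fe_params,
        D=D,
        sigma2=float(res.scale),
        loglik=float(res.llf),
        n_re=1 if random_effects == "intercept" else 2,
        fixed_effects=fixed_effects,
        centering=centering,
        reml=reml,
    )


def predict_random_effects(
    estimates: LMEEstimates, data: pd.DataFrame
) -> pd.DataFrame:
    """Empirical BLUPs ``b_i = D Z_i' V_i^{-1} (y_i - X_i beta)``.

    Shrinks each subject's raw deviation toward zero in proportion to the
    information their observations carry.  Returns one (id, b0, b1) row per
    subject.
    """
    data = validate_longitudinal(data)
    X = _design(data, estimates.fixed_effects, estimates.centering)
    resid = data["response"].astype(float).to_numpy() - X.to_numpy() @ np.asarray(
        estimates.beta.reindex(X.columns), dtype=float
    )
    D, s2 = estimates.D, estimates.sigma2
    rows = []
    for sid, idx in data.groupby("id", sort=False).indices.items():
        t = data["time"].to_numpy(dtype=float)[idx]
        Z = np.column_stack([np.ones(t.size), t])
        V = Z @ D @ Z.T + s2 * np.eye(t.size)
        b = D @ Z.T @ np.linalg.solve(V, resid[idx])
        rows.append({"id": sid, "b0": float(b[0]), "b1": float(b[1])})
    return pd.DataFrame(rows)


def lrt_random_effects(fit_nested: LMEEstimates, fit_full: LMEEstimates):
    """LRT for random-effect inclusion between nested fits.

    df = difference in variance-parameter counts (q(q+1)/2 plus residual).
    The chi-square reference ignores the boundary constraint (variances at
    zero), which makes the test conservative.
    Returns (statistic, df, p-value).
    """
    if fit_nested.fixed_effects != fit_full.fixed_effects:
        raise ValueError("fits have different fixed effects; not nested")
    if fit_nested.n_re > fit_full.n_re:
        raise ValueError("first argument must be the nested (smaller) model")
    if fit_nested.reml != fit_full.reml:
        raise ValueError("fits use different estimation criteria")
    n_var = lambda q: q * (q + 1) // 2
    df = n_var(fit_full.n_re) - n_var(fit_nested.n_re)
    stat = max(2.0 * (fit_full.loglik - fit_nested.loglik), 0.0)
    if df == 0:
        return stat, 0, 1.0 if stat <= 1e-8 else 0.0
    return stat, df, float(stats.chi2.sf(stat, df))
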