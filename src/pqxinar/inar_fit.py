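"""Fitting and comparing INAR(1) models on observed count series.

Estimation routes:

* :func:`cml_fit` — conditional maximum likelihood: maximize
  sum_{t=2..T} log P(X_t | X_{t-1}) over (p, innovation parameters), with the
  transition terms evaluated by log-sum-exp.  Works for every registered
  innovation family; standard errors come from the inverse observed
  information.
* :func:`yw_fit` — Yule-Walker for PQX innovations: p from the lag-1 sample
  autocorrelation, then (alpha, theta) from matching the sample mean and
  sample dispersion index to the stationary process moments.  By construction
  the fitted process reproduces the sample mean and dispersion exactly.

Model selection uses AIC = 2k + 2(-l) and BIC = k log T + 2(-l) with T the
full series length.  Diagnostics: standardized Pearson residuals
e_t = (x_t - E[X_t|x_{t-1}]) / sd(X_t|x_{t-1}) (mean 0, variance 1 and no
autocorrelation under a correctly specified model), the asymptotic
over-dispersion test against a Poisson INAR(1) null, and the one-step-ahead
conditional-mean forecast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .exceptions import DomainError, ParameterError, YWIncompatibleError
from .inar import (
    CountSeries,
    INARModel,
    InnovationLaw,
    PQXInnovation,
    get_family,
    pqx_process_moments,
    process_moments,
)
from .pqx import PQXParams

__all__ = [
    "INARFitResult",
    "ResidualDiagnostics",
    "conditional_loglik",
    "cml_fit",
    "yw_fit",
    "compare_models",
    "pearson_residuals",
    "overdispersion_test",
    "forecast_one_step",
]


@dataclass
class INARFitResult:
    """Outcome of an INAR(1) fit."""

    model: INARModel
    method: str  # CML | YW
    neg_loglik: float | None = None
    standard_errors: dict = field(default_factory=dict)
    converged: bool = True
    message: str = ""
    n_obs: int = 0  # full series length T

    @property
    def k_params(self) -> int:
        return 1 + self.model.innovation.n_params

    @property
    def aic(self) -> float:
        if self.neg_loglik is None:
            return math.nan
        return 2.0 * self.k_params + 2.0 * self.neg_loglik

    @property
    def bic(self) -> float:
        if self.neg_loglik is None:
            return math.nan
        return self.k_params * math.log(self.n_obs) + 2.0 * self.neg_loglik


@dataclass
class ResidualDiagnostics:
    """Standardized Pearson residuals e_2..e_T and their summary statistics."""

    residuals: np.ndarray
    mean: float
    variance: float
    acf: np.ndarray  # lags 1..H


def conditional_loglik(series: CountSeries, p: float, innovation: InnovationLaw) -> float:
    """sum_{t=2..T} log P(X_t = x_t | X_{t-1} = x_{t-1}), vectorized."""
    x = series.values
    xt, xp = x[1:], x[:-1]
    imax = np.minimum(xt, xp)
    M = int(imax.max())
    i = np.arange(M + 1)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        lb = stats.binom.logpmf(i, xp[:, None], p)
        le = innovation.logpmf(xt[:, None] - i)
        terms = lb + le
    terms[i > imax[:, None]] = -np.inf
    # row-wise log-sum-exp
    m = np.max(terms, axis=1)
    if np.any(~np.isfinite(m)):
        return -np.inf
    return float(np.sum(m + np.log(np.sum(np.exp(terms - m[:, None]), axis=1))))


def _yw_start(series: CountSeries, family: type) -> tuple[float, InnovationLaw]:
    """Warm start: p from clipped lag-1 ACF, innovation from implied moments."""
    p0 = min(max(series.autocorrelation(1), 0.0), 0.95)
    mu_e = series.mean * (1.0 - p0)
    var_e = max(series.variance * (1.0 - p0**2) - p0 * mu_e, 1e-6)
    return p0, family.from_moments(mu_e, var_e)


def cml_fit(
    series: CountSeries,
    family: str = "pqx",
    init: tuple[float, InnovationLaw] | None = None,
) -> INARFitResult:
    """Conditional maximum likelihood for any registered innovation family.

    Optimizes on transformed parameters (logit for p and probability-type
    innovation parameters, log for positive ones) so the optimizer is
    unconstrained; standard errors are reported on the natural scale.
    """
    if series.T < 3:
        raise DomainError("CML needs at least 3 observations")
    if np.all(series.values == series.values[0]):
        raise DomainError("constant series: conditional likelihood is degenerate")
    cls = get_family(family) if isinstance(family, str) else family
    if init is None:
        init = _yw_start(series, cls)
    p0, innov0 = init
    p0 = min(max(p0, 1e-4), 1.0 - 1e-4)
    z0 = np.concatenate([[math.log(p0 / (1.0 - p0))], innov0.to_unconstrained()])

    def unpack(z):
        p = 1.0 / (1.0 + math.exp(-float(np.clip(z[0], -30, 30))))
        innov = cls.from_unconstrained(np.clip(z[1:], -30, 30))
        return p, innov

    def negll(z):
        try:
            p, innov = unpack(z)
            return -conditional_loglik(series, p, innov)
        except (ParameterError, OverflowError, FloatingPointError):
            return np.inf

    res = optimize.minimize(negll, z0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000})
    p_hat, innov_hat = unpack(res.x)
    model = INARModel(p=p_hat, innovation=innov_hat)
    ses = _cml_ses(series, model, cls)
    return INARFitResult(
        model=model,
        method="CML",
        neg_loglik=float(res.fun),
        standard_errors=ses,
        converged=bool(res.success),
        message=str(res.message),
        n_obs=series.T,
    )


def _cml_ses(series: CountSeries, model: INARModel, cls: type) -> dict:
    """SEs on the natural scale from the inverse observed information."""
    names = ("p",) + tuple(cls.param_names)
    theta0 = np.array([model.p, *model.innovation.params], dtype=float)

    def negll_nat(v):
        try:
            if not 0.0 <= v[0] < 1.0:
                return np.inf
            innov = cls(*v[1:])
            return -conditional_loglik(series, float(v[0]), innov)
        except (ParameterError, ValueError):
            return np.inf

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess1(theta0, negll_nat)
            cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
            raise np.linalg.LinAlgError
        return dict(zip(names, np.sqrt(diag).tolist()))
    except (np.linalg.LinAlgError, ValueError):
        return {}


def yw_fit(series: CountSeries) -> INARFitResult:
    """Yule-Walker estimation of an INARPQX(1) model.

    p from the lag-1 autocorrelation (clipped to [0,1) with a warning when
    negative), then alpha from matching the sample dispersion index and theta
    from matching the sample mean:

        c = (DI - 1)(1 + p) / ((1 - p) Xbar)
        (c - 1) alpha^2 + (6c - 8) alpha + (9c - 3) = 0
        alpha = [4 - 3c - sqrt(13 - 12c)] / (c - 1)
        theta = (alpha + 3) / (Xbar (1 + alpha)(1 - p)).

    Raises :class:`YWIncompatibleError` when the discriminant is negative or
    alpha <= 0 (e.g. under-dispersed series).
    """
    if series.T < 3:
        raise DomainError("YW needs at least 3 observations")
    p_hat = series.autocorrelation(1)
    if p_hat < 0.0:
        warnings.warn(
            f"lag-1 autocorrelation {p_hat:.4f} < 0 clipped to 0 (model space p in [0,1))",
            RuntimeWarning,
        )
        p_hat = 0.0
    if p_hat >= 1.0:
        warnings.warn("lag-1 autocorrelation >= 1 clipped below 1", RuntimeWarning)
        p_hat = 1.0 - 1e-8
    xbar, di = series.mean, series.dispersion_index
    if di <= 1.0:
        raise YWIncompatibleError(
            f"YW moments incompatible: sample dispersion index {di:.4f} <= 1"
        )
    c = (di - 1.0) * (1.0 + p_hat) / ((1.0 - p_hat) * xbar)
    disc = 13.0 - 12.0 * c
    if disc < 0:
        raise YWIncompatibleError(
            f"YW moments incompatible: negative square-root argument 13-12c = {disc:.4f}"
        )
    if abs(c - 1.0) < 1e-12:
        alpha = 3.0  # the quadratic degenerates to -2 alpha + 6 = 0
    else:
        alpha = (4.0 - 3.0 * c - math.sqrt(disc)) / (c - 1.0)
    if alpha <= 0:
        raise YWIncompatibleError(
            f"YW moments incompatible: alpha estimate {alpha:.4f} <= 0"
        )
    theta = (alpha + 3.0) / (xbar * (1.0 + alpha) * (1.0 - p_hat))
    model = INARModel(p=p_hat, innovation=PQXInnovation(alpha, theta))
    nll = -conditional_loglik(series, model.p, model.innovation)
    return INARFitResult(
        model=model, method="YW", neg_loglik=nll, n_obs=series.T,
    )


def compare_models(series: CountSeries, families: list[str] | None = None) -> pd.DataFrame:
    """CML-fit each family and tabulate -l / AIC / BIC / fitted process moments.

    Returns a DataFrame sorted by AIC (lowest = preferred); per-family fit
    failures are recorded in the table rather than raised.
    """
    if families is None:
        families = ["pqx", "nb", "geometric", "pl", "poisson"]
    if len(families) < 2:
        raise DomainError("model comparison needs at least 2 families")
    rows = []
    for fam in families:
        try:
            fit = cml_fit(series, family=fam)
            pm = process_moments(fit.model)
            rows.append({
                "Model": f"INAR{fam.upper()}(1)",
                "family": fam,
                "estimates": (fit.model.p, *fit.model.innovation.params),
                "neg_loglik": fit.neg_loglik,
                "AIC": fit.aic,
                "BIC": fit.bic,
                "mu_X": pm["mean"],
                "sigma2_X": pm["variance"],
                "DI_X": pm["dispersion_index"],
                "converged": fit.converged,
                "error": "",
            })
        except Exception as exc:  # noqa: BLE001 - per-family failures are data
            rows.append({
                "Model": f"INAR{fam.upper()}(1)", "family": fam,
                "estimates": None, "neg_loglik": math.nan, "AIC": math.nan,
                "BIC": math.nan, "mu_X": math.nan, "sigma2_X": math.nan,
                "DI_X": math.nan, "converged": False, "error": str(exc),
            })
    table = pd.DataFrame(rows).sort_values("AIC", na_position="last")
    return table.reset_index(drop=True)


def pearson_residuals(series: CountSeries, model: INARModel, n_lags: int = 10) -> ResidualDiagnostics:
    """Standardized Pearson residuals e_t for t = 2..T under a fitted model."""
    x = series.values.astype(float)
    p = model.p
    mu_e, var_e = model.innovation.mean, model.innovation.variance
    cond_mean = p * x[:-1] + mu_e
    cond_var = p * (1.0 - p) * x[:-1] + var_e
    if np.any(cond_var <= 0):
        raise ParameterError("non-positive conditional variance")
    e = (x[1:] - cond_mean) / np.sqrt(cond_var)
    n = e.size
    ec = e - e.mean()
    denom = float(np.sum(ec**2))
    acf = np.array([np.sum(ec[h:] * ec[:-h]) / denom for h in range(1, n_lags + 1)])
    return ResidualDiagnostics(
        residuals=e,
        mean=float(np.mean(e)),
        variance=float(np.var(e)),
        acf=acf,
    )


def overdispersion_test(series: CountSeries) -> dict:
    """Asymptotic test of equi-dispersion against over-dispersion.

    Under a Poisson INAR(1) null the empirical dispersion index satisfies
    sqrt(T) (DI_hat - 1) -> N(0, 2 (1+p^2)/(1-p^2)); the statistic plugs in
    the lag-1 sample autocorrelation for p and the one-sided p-value is the
    upper normal tail.
    """
    if series.T < 30:
        raise DomainError("the asymptotic over-dispersion test needs T >= 30")
    di = series.dispersion_index
    p_hat = min(max(series.autocorrelation(1), 0.0), 1.0 - 1e-8)
    sigma2 = 2.0 * (1.0 + p_hat**2) / (1.0 - p_hat**2)
    statistic = math.sqrt(series.T) * (di - 1.0) / math.sqrt(sigma2)
    return {"statistic": statistic, "p_value": float(stats.norm.sf(statistic))}


def forecast_one_step(series: CountSeries, model: INARModel) -> np.ndarray:
    """One-step-ahead predictions: X1_hat = stationary mean, then conditional means.

    X_hat_1 = mu_X and X_hat_t = p x_{t-1} + mu_eps for t >= 2; predictions
    are real-valued (not rounded).
    """
    x = series.values.astype(float)
    out = np.empty(series.T, dtype=float)
    out[0] = process_moments(model)["mean"]
    out[1:] = model.p * x[:-1] + model.innovation.mean
    return out
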