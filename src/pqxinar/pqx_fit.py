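"""Parameter estimation for iid PQX samples.

Three routes are provided:

* :func:`fit_mle` — numerical maximization of the exact log-likelihood on the
  log-parameter scale, with analytic score, observed-information standard
  errors (delta method back to the natural scale) and Wald intervals;
* :func:`fit_mm` — the closed-form method-of-moments inversion of the first
  two raw moments, together with its asymptotic theory (for fixed alpha the
  moment estimator of theta is positively biased but consistent and
  asymptotically normal with variance v^2(theta)/n, see
  :func:`mm_asymptotics`);
* :func:`fit_em` — an expectation-maximization scheme.  The quasi-xgamma
  mixing density is a two-component mixture of an exponential(theta) and a
  gamma(3, theta), so the natural complete data are (x, lambda, z) with z the
  component indicator.  The complete-data log-likelihood is linear in z and
  lambda, hence the E-step needs only the closed-form posterior expectations

      w_i = P(z_i = 1 | x_i) = 2 alpha (1+theta)^2
            / (2 alpha (1+theta)^2 + theta^2 (x_i+1)(x_i+2))
      u_i = E[lambda | x_i]

  and the M-step is exact:

      alpha <- w_bar / (1 - w_bar),   theta <- (3 - 2 w_bar) / u_bar.

  As a genuine EM this iteration never decreases the observed-data
  log-likelihood (checked at every step), and its fixed points solve the
  score equations, so it agrees with :func:`fit_mle` on well-behaved samples.
  The companion conditional expectations t_i = E[lambda^2/(2a+t^2 lambda^2)|x]
  and s_i = E[1/(2a+t^2 lambda^2)|x] (note w_i = 2 alpha s_i) are exposed by
  :func:`em_expectations`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from . import pqx
from .exceptions import DomainError, EMNumericalError, MomentsIncompatibleError
from .pqx import PQXParams

__all__ = [
    "IIDSample",
    "FitResult",
    "pqx_loglik",
    "score",
    "fit_mle",
    "fit_mm",
    "mm_invert",
    "mm_asymptotics",
    "fit_em",
    "em_expectations",
]


@dataclass(frozen=True)
class IIDSample:
    """An iid sample of non-negative integer counts."""

    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 1 or arr.size < 2:
            raise DomainError("sample must be a 1-d vector with at least 2 observations")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise DomainError("sample entries must be non-negative integers")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def n(self) -> int:
        return self.counts.size

    @property
    def m1(self) -> float:
        """First raw sample moment (divisor n)."""
        return float(np.mean(self.counts))

    @property
    def m2(self) -> float:
        """Second raw sample moment (divisor n)."""
        return float(np.mean(self.counts.astype(float) ** 2))


@dataclass
class FitResult:
    """Outcome of an iid PQX fit."""

    params: PQXParams
    method: str  # MLE | MM | EM
    loglik: float | None = None
    standard_errors: dict = field(default_factory=dict)
    converged: bool = True
    iterations: int = 0
    message: str = ""

    def conf_int(self, level: float = 0.95) -> dict:
        """Wald intervals estimate +/- z_{p/2} * SE on the natural scale."""
        if not self.standard_errors:
            raise ValueError(f"{self.method} fit carries no standard errors")
        z = stats.norm.ppf(0.5 + level / 2.0)
        est = {"alpha": self.params.alpha, "theta": self.params.theta}
        return {
            k: (est[k] - z * se, est[k] + z * se)
            for k, se in self.standard_errors.items()
        }


def pqx_loglik(sample: IIDSample, params: PQXParams) -> float:
    """Exact log-likelihood of an iid PQX sample."""
    x = sample.counts
    a, t = params.alpha, params.theta
    num = 2.0 * a * t * (t + 1.0) ** 2 + t**3 * (x + 1.0) * (x + 2.0)
    return float(
        np.sum(np.log(num))
        - sample.n * math.log(2.0 * (a + 1.0))
        - math.log1p(t) * np.sum(x + 3.0)
    )


def score(sample: IIDSample, params: PQXParams) -> np.ndarray:
    """Score vector (d/d alpha, d/d theta) of the log-likelihood."""
    x = sample.counts.astype(float)
    a, t = params.alpha, params.theta
    denom = 2.0 * a * t * (t + 1.0) ** 2 + t**3 * (x + 1.0) * (x + 2.0)
    d_alpha = float(np.sum(2.0 * t * (t + 1.0) ** 2 / denom) - sample.n / (a + 1.0))
    d_theta = float(
        np.sum(
            (2.0 * a * (t + 1.0) ** 2 + 4.0 * a * t * (t + 1.0)
             + 3.0 * t**2 * (x + 1.0) * (x + 2.0)) / denom
        )
        - np.sum(x + 3.0) / (t + 1.0)
    )
    return np.array([d_alpha, d_theta])


_LOG_BOUND = 20.0  # log-parameter box; e^-20 ~ 2e-9 acts as the alpha=0 boundary


def _mle_start(sample: IIDSample) -> PQXParams:
    """MM start when admissible, else the fallback (alpha=1, theta=1/m1)."""
    try:
        return fit_mm(sample).params
    except MomentsIncompatibleError:
        return PQXParams(alpha=1.0, theta=1.0 / max(sample.m1, 1e-8))


def fit_mle(sample: IIDSample, init: PQXParams | None = None) -> FitResult:
    """Maximum likelihood on the log-parameter scale with analytic gradient."""
    if np.all(sample.counts == sample.counts[0]):
        return FitResult(
            params=PQXParams(1.0, 1.0),
            method="MLE",
            loglik=None,
            converged=False,
            message="degenerate sample (all observations equal)",
        )
    start = init if init is not None else _mle_start(sample)
    z0 = np.log([max(start.alpha, 1e-6), start.theta])

    def negll(z):
        p = PQXParams(*np.exp(np.clip(z, -_LOG_BOUND, _LOG_BOUND)))
        return -pqx_loglik(sample, p)

    def grad(z):
        zc = np.clip(z, -_LOG_BOUND, _LOG_BOUND)
        p = PQXParams(*np.exp(zc))
        return -score(sample, p) * np.exp(zc)  # chain rule d/d log-param

    res = optimize.minimize(
        negll, z0, jac=grad, method="L-BFGS-B",
        bounds=[(-_LOG_BOUND, _LOG_BOUND)] * 2,
    )
    zhat = np.clip(res.x, -_LOG_BOUND, _LOG_BOUND)
    params = PQXParams(*np.exp(zhat))
    ses = _observed_info_ses(sample, params)
    msg = res.message if isinstance(res.message, str) else str(res.message)
    converged = bool(res.success)
    if zhat[0] >= _LOG_BOUND - 1e-6:
        # flat likelihood toward the geometric (alpha -> inf) limit: alpha is
        # effectively unidentified, report the fit but flag it
        converged = False
        msg = "alpha estimate at the upper parameter bound (geometric limit); " + msg
    if np.all(sample.counts == 0):
        msg = "all-zero sample: estimate at the parameter boundary; " + msg
        warnings.warn("all-zero sample pushes the MLE to the boundary", RuntimeWarning)
    return FitResult(
        params=params,
        method="MLE",
        loglik=-res.fun,
        standard_errors=ses,
        converged=converged,
        iterations=int(res.nit),
        message=msg,
    )


def _observed_info_ses(sample: IIDSample, params: PQXParams) -> dict:
    """SEs from the inverse observed information at the estimate (natural scale)."""

    def negll_nat(v):
        if v[0] < 0 or v[1] <= 0:
            return np.inf
        return -pqx_loglik(sample, PQXParams(float(v[0]), float(v[1])))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess1(np.array([params.alpha, params.theta]), negll_nat)
            cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
            raise np.linalg.LinAlgError
        ses = np.sqrt(diag)
        return {"alpha": float(ses[0]), "theta": float(ses[1])}
    except (np.linalg.LinAlgError, ValueError):
        return {}


def mm_invert(m1: float, m2: float) -> PQXParams:
    """Closed-form moment inversion: first two raw moments -> (alpha, theta).

    Solving mean = m1 and second raw moment = m2 gives

        alpha = [-7 m1^2 + sqrt(25 m1^4 + 12 m1^3 - 12 m1^2 m2) - 3(m1 - m2)]
                / [2 m1^2 + m1 - m2]
        theta = (alpha + 3) / (m1 (alpha + 1)).

    Raises :class:`MomentsIncompatibleError` when the square-root argument is
    negative or an estimate is not positive (typical for under-dispersed
    samples); alpha = 0 exactly is admitted as the NB(3, .) boundary.
    """
    disc = 25.0 * m1**4 + 12.0 * m1**3 - 12.0 * m1**2 * m2
    if disc < 0:
        raise MomentsIncompatibleError(
            f"moments incompatible with PQX: square-root argument "
            f"25*m1^4+12*m1^3-12*m1^2*m2 = {disc:.6g} < 0"
        )
    denom = 2.0 * m1**2 + m1 - m2
    if denom == 0:
        raise MomentsIncompatibleError(
            "moments incompatible with PQX: zero denominator 2*m1^2 + m1 - m2"
        )
    alpha = (-7.0 * m1**2 + math.sqrt(disc) - 3.0 * (m1 - m2)) / denom
    if alpha < 0:
        raise MomentsIncompatibleError(
            f"moments incompatible with PQX: alpha estimate {alpha:.6g} < 0 "
            f"(under-dispersed input)"
        )
    theta = (alpha + 3.0) / (m1 * (1.0 + alpha))
    if theta <= 0:
        raise MomentsIncompatibleError(
            f"moments incompatible with PQX: theta estimate {theta:.6g} <= 0"
        )
    return PQXParams(alpha, theta)


def fit_mm(sample: IIDSample) -> FitResult:
    """Method-of-moments fit of an iid sample via :func:`mm_invert`."""
    params = mm_invert(sample.m1, sample.m2)
    return FitResult(params=params, method="MM", loglik=pqx_loglik(sample, params))


def mm_asymptotics(params: PQXParams) -> dict:
    """Asymptotic variance of the moment estimator of theta at fixed alpha.

    sqrt(n) (theta_hat - theta) -> N(0, v^2) with
    v^2 = theta^2 [alpha(8+alpha) + (alpha+1)(alpha+3)theta + 3] / (alpha+3)^2.
    """
    a, t = params.alpha, params.theta
    v2 = t**2 * (a * (8.0 + a) + (a + 1.0) * (a + 3.0) * t + 3.0) / (a + 3.0) ** 2
    return {"v_squared": v2}


def em_expectations(x: np.ndarray, params: PQXParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form E-step posterior expectations (t_i, s_i, u_i) given counts x."""
    a, t = params.alpha, params.theta
    xf = np.asarray(x, dtype=float)
    denom = 2.0 * a * (1.0 + t) ** 2 + t**2 * (xf + 1.0) * (xf + 2.0)
    t_i = (xf + 1.0) * (xf + 2.0) / denom
    s_i = (1.0 + t) ** 2 / denom
    u_i = (
        (xf + 1.0)
        * (2.0 * a * (1.0 + t) ** 2 + t**2 * (xf + 2.0) * (xf + 3.0))
        / ((1.0 + t) * denom)
    )
    return t_i, s_i, u_i


def fit_em(
    sample: IIDSample,
    init: PQXParams | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> FitResult:
    """EM-type estimation of (alpha, theta); see the module docstring.

    The observed-data log-likelihood is tracked and required to be
    non-decreasing (within 1e-10 slack) along the iteration.
    """
    if tol <= 0:
        raise DomainError("tol must be > 0")
    params = init if init is not None else _mle_start(sample)
    x = sample.counts
    ll_prev = pqx_loglik(sample, params)
    for h in range(1, max_iter + 1):
        _, s_i, u_i = em_expectations(x, params)
        w_bar = float(np.mean(2.0 * params.alpha * s_i))
        u_bar = float(np.mean(u_i))
        if not 0.0 <= w_bar < 1.0:
            raise EMNumericalError(
                f"EM alpha update leaves the parameter space at iteration {h}: "
                f"posterior component weight w_bar = {w_bar:.6g}",
                iteration=h,
            )
        if u_bar <= 0.0 or 3.0 - 2.0 * w_bar <= 0.0:
            raise EMNumericalError(
                f"EM theta update undefined at iteration {h}: "
                f"u_bar = {u_bar:.6g}, w_bar = {w_bar:.6g}",
                iteration=h,
            )
        alpha_new = w_bar / (1.0 - w_bar)
        theta_new = (3.0 - 2.0 * w_bar) / u_bar
        new = PQXParams(alpha_new, theta_new)
        ll_new = pqx_loglik(sample, new)
        if ll_new < ll_prev - 1e-10:
            raise EMNumericalError(
                f"observed log-likelihood decreased at iteration {h} "
                f"({ll_prev:.10g} -> {ll_new:.10g})",
                iteration=h,
            )
        rel_change = max(
            abs(alpha_new - params.alpha) / max(abs(params.alpha), 1e-12),
            abs(theta_new - params.theta) / max(abs(params.theta), 1e-12),
        )
        params, ll_prev = new, ll_new
        if rel_change < tol:
            return FitResult(
                params=params, method="EM", loglik=ll_prev,
                standard_errors=_observed_info_ses(sample, params),
                converged=True, iterations=h,
            )
    return FitResult(
        params=params, method="EM", loglik=ll_prev,
        standard_errors=_observed_info_ses(sample, params),
        converged=False, iterations=max_iter,
        message=f"no convergence within {max_iter} iterations",
    )
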