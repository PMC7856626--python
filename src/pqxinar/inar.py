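"""INAR(1) machinery: binomial thinning, innovation families, simulation,
transition probabilities and exact process moments.

The process is X_t = p o X_{t-1} + eps_t, where `o` is binomial thinning
(p o X = sum of X iid Bernoulli(p)) and the innovations eps_t are iid from a
pluggable innovation law.  With PQX innovations the process is INARPQX(1),
the over-dispersed model this package is built around; Poisson,
Poisson-Lindley, geometric and negative binomial innovations are provided as
the standard comparison families.  The stationary process has

    mean            mu_eps / (1 - p)
    variance        (p mu_eps + sigma2_eps) / (1 - p^2)
    dispersion      (DI_eps + p) / (1 + p)

and lag-h autocorrelation p^h for 0 <= p < 1.
"""

from __future__ import annotations

import abc
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from . import pqx
from .exceptions import DomainError, ParameterError
from .pqx import PQXParams

__all__ = [
    "InnovationLaw",
    "PoissonInnovation",
    "PoissonLindleyInnovation",
    "GeometricInnovation",
    "NegBinInnovation",
    "PQXInnovation",
    "INNOVATION_FAMILIES",
    "get_family",
    "INARModel",
    "CountSeries",
    "binomial_thinning",
    "simulate",
    "transition_probability",
    "transition_logpmf",
    "process_moments",
    "pqx_process_moments",
    "conditional_moments",
]


class InnovationLaw(abc.ABC):
    """Contract every innovation family satisfies.

    Concrete families expose a vectorized (log-)pmf on the non-negative
    integers, exact mean/variance, a sampler, and parameter packing helpers so
    the conditional-likelihood optimizer can work on an unconstrained scale
    without knowing the family.
    """

    name: str = ""
    param_names: tuple = ()

    @abc.abstractmethod
    def logpmf(self, k) -> np.ndarray:
        """log P(eps = k); -inf for k < 0 (array-safe, no domain error)."""

    def pmf(self, k) -> np.ndarray:
        return np.exp(self.logpmf(k))

    @property
    @abc.abstractmethod
    def mean(self) -> float: ...

    @property
    @abc.abstractmethod
    def variance(self) -> float: ...

    @property
    def dispersion_index(self) -> float:
        return self.variance / self.mean

    @abc.abstractmethod
    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray: ...

    @property
    @abc.abstractmethod
    def params(self) -> tuple: ...

    @abc.abstractmethod
    def to_unconstrained(self) -> np.ndarray:
        """Map parameters to R^k for optimization."""

    @classmethod
    @abc.abstractmethod
    def from_unconstrained(cls, z: np.ndarray) -> "InnovationLaw": ...

    @classmethod
    @abc.abstractmethod
    def from_moments(cls, mean: float, var: float) -> "InnovationLaw":
        """A moment-matched starting value; must always return a valid law."""

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _nonneg_int_mask(k) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(k)
    valid = (arr >= 0) & (arr == np.floor(arr))
    return arr, valid


class PoissonInnovation(InnovationLaw):
    name = "poisson"
    param_names = ("lambda",)

    def __init__(self, lam: float):
        if not (np.isfinite(lam) and lam > 0):
            raise ParameterError(f"lambda must be > 0, got {lam}")
        self.lam = float(lam)

    def logpmf(self, k):
        arr, valid = _nonneg_int_mask(k)
        out = np.where(valid, stats.poisson.logpmf(np.where(valid, arr, 0), self.lam), -np.inf)
        return out if out.ndim else float(out)

    @property
    def mean(self):
        return self.lam

    @property
    def variance(self):
        return self.lam

    def sample(self, n, rng):
        return rng.poisson(self.lam, size=n)

    @property
    def params(self):
        return (self.lam,)

    def to_unconstrained(self):
        return np.array([math.log(self.lam)])

    @classmethod
    def from_unconstrained(cls, z):
        return cls(math.exp(float(z[0])))

    @classmethod
    def from_moments(cls, mean, var):
        return cls(max(mean, 1e-6))


class PoissonLindleyInnovation(InnovationLaw):
    """Poisson mixed over a Lindley(theta) rate: pmf theta^2 (k+theta+2)/(theta+1)^(k+3)."""

    name = "pl"
    param_names = ("theta",)

    def __init__(self, theta: float):
        if not (np.isfinite(theta) and theta > 0):
            raise ParameterError(f"theta must be > 0, got {theta}")
        self.theta = float(theta)

    def logpmf(self, k):
        arr, valid = _nonneg_int_mask(k)
        t = self.theta
        kk = np.where(valid, arr, 0).astype(float)
        out = np.where(
            valid,
            2.0 * math.log(t) + np.log(kk + t + 2.0) - (kk + 3.0) * math.log1p(t),
            -np.inf,
        )
        return out if out.ndim else float(out)

    @property
    def mean(self):
        t = self.theta
        return (t + 2.0) / (t * (t + 1.0))

    @property
    def variance(self):
        t = self.theta
        # second factorial moment 2(t+3)/(t^2(t+1))
        m = self.mean
        return 2.0 * (t + 3.0) / (t**2 * (t + 1.0)) + m - m**2

    def sample(self, n, rng):
        # Lindley(theta) rate: exponential(theta) w.p. theta/(theta+1), else gamma(2, theta)
        t = self.theta
        expo = rng.random(n) < t / (t + 1.0)
        lam = np.where(
            expo,
            rng.exponential(scale=1.0 / t, size=n),
            rng.gamma(shape=2.0, scale=1.0 / t, size=n),
        )
        return rng.poisson(lam)

    @property
    def params(self):
        return (self.theta,)

    def to_unconstrained(self):
        return np.array([math.log(self.theta)])

    @classmethod
    def from_unconstrained(cls, z):
        return cls(math.exp(float(z[0])))

    @classmethod
    def from_moments(cls, mean, var):
        m = max(mean, 1e-6)
        # solve m*theta^2 + (m-1)*theta - 2 = 0 for theta > 0
        theta = ((1.0 - m) + math.sqrt((m - 1.0) ** 2 + 8.0 * m)) / (2.0 * m)
        return cls(theta)


class GeometricInnovation(InnovationLaw):
    """Geometric on {0,1,...} with success probability theta: pmf theta (1-theta)^k."""

    name = "geometric"
    param_names = ("theta",)

    def __init__(self, theta: float):
        if not (np.isfinite(theta) and 0 < theta < 1):
            raise ParameterError(f"theta must be in (0,1), got {theta}")
        self.theta = float(theta)

    def logpmf(self, k):
        arr, valid = _nonneg_int_mask(k)
        kk = np.where(valid, arr, 0).astype(float)
        out = np.where(valid, math.log(self.theta) + kk * math.log1p(-self.theta), -np.inf)
        return out if out.ndim else float(out)

    @property
    def mean(self):
        return (1.0 - self.theta) / self.theta

    @property
    def variance(self):
        return (1.0 - self.theta) / self.theta**2

    def sample(self, n, rng):
        return rng.geometric(self.theta, size=n) - 1

    @property
    def params(self):
        return (self.theta,)

    def to_unconstrained(self):
        return np.array([math.log(self.theta / (1.0 - self.theta))])

    @classmethod
    def from_unconstrained(cls, z):
        return cls(1.0 / (1.0 + math.exp(-float(z[0]))))

    @classmethod
    def from_moments(cls, mean, var):
        return cls(min(max(1.0 / (1.0 + max(mean, 1e-6)), 1e-6), 1 - 1e-6))


class NegBinInnovation(InnovationLaw):
    """NB(n, pi): pmf C(n+k-1, k) (1-pi)^k pi^n (pi = success probability)."""

    name = "nb"
    param_names = ("n", "pi")

    def __init__(self, n: float, pi: float):
        if not (np.isfinite(n) and n > 0):
            raise ParameterError(f"n must be > 0, got {n}")
        if not (np.isfinite(pi) and 0 < pi < 1):
            raise ParameterError(f"pi must be in (0,1), got {pi}")
        self.n = float(n)
        self.pi = float(pi)
        self._dist = stats.nbinom(self.n, self.pi)

    def logpmf(self, k):
        arr, valid = _nonneg_int_mask(k)
        out = np.where(valid, self._dist.logpmf(np.where(valid, arr, 0)), -np.inf)
        return out if out.ndim else float(out)

    @property
    def mean(self):
        return self.n * (1.0 - self.pi) / self.pi

    @property
    def variance(self):
        return self.n * (1.0 - self.pi) / self.pi**2

    def sample(self, n, rng):
        return rng.negative_binomial(self.n, self.pi, size=n)

    @property
    def params(self):
        return (self.n, self.pi)

    def to_unconstrained(self):
        return np.array([math.log(self.n), math.log(self.pi / (1.0 - self.pi))])

    @classmethod
    def from_unconstrained(cls, z):
        return cls(math.exp(float(z[0])), 1.0 / (1.0 + math.exp(-float(z[1]))))

    @classmethod
    def from_moments(cls, mean, var):
        m = max(mean, 1e-6)
        if var <= m * (1 + 1e-6):
            var = m * 1.5  # fall back to a mildly over-dispersed start
        pi = m / var
        n = m * pi / (1.0 - pi)
        return cls(n, pi)


class PQXInnovation(InnovationLaw):
    """PQX(alpha, theta) innovations — the over-dispersed law of this package."""

    name = "pqx"
    param_names = ("alpha", "theta")

    def __init__(self, alpha: float, theta: float):
        self.pqx_params = PQXParams(alpha, theta)
        self.alpha = self.pqx_params.alpha
        self.theta = self.pqx_params.theta

    def logpmf(self, k):
        arr, valid = _nonneg_int_mask(k)
        out = np.where(valid, pqx.logpmf(np.where(valid, arr, 0), self.pqx_params), -np.inf)
        return out if out.ndim else float(out)

    @property
    def mean(self):
        return pqx.mean(self.pqx_params)

    @property
    def variance(self):
        return pqx.variance(self.pqx_params)

    @property
    def dispersion_index(self):
        return pqx.dispersion_index(self.pqx_params)

    def sample(self, n, rng):
        return pqx.rvs(n, self.pqx_params, seed=rng)

    @property
    def params(self):
        return (self.alpha, self.theta)

    def to_unconstrained(self):
        return np.array([math.log(max(self.alpha, 1e-9)), math.log(self.theta)])

    @classmethod
    def from_unconstrained(cls, z):
        return cls(math.exp(float(z[0])), math.exp(float(z[1])))

    @classmethod
    def from_moments(cls, mean, var):
        from .pqx_fit import mm_invert
        from .exceptions import MomentsIncompatibleError

        m1 = max(mean, 1e-6)
        try:
            p = mm_invert(m1, var + m1**2)
            return cls(p.alpha, p.theta)
        except MomentsIncompatibleError:
            return cls(1.0, 2.0 / m1)


INNOVATION_FAMILIES: dict[str, type] = {
    cls.name: cls
    for cls in (
        PoissonInnovation,
        PoissonLindleyInnovation,
        GeometricInnovation,
        NegBinInnovation,
        PQXInnovation,
    )
}


def get_family(name: str) -> type:
    try:
        return INNOVATION_FAMILIES[name]
    except KeyError:
        raise KeyError(
            f"unknown innovation family {name!r}; "
            f"known: {sorted(INNOVATION_FAMILIES)}"
        ) from None


@dataclass(frozen=True)
class INARModel:
    """An INAR(1) model: thinning probability p in [0, 1) plus an innovation law."""

    p: float
    innovation: InnovationLaw

    def __post_init__(self):
        if not (np.isfinite(self.p) and 0.0 <= self.p < 1.0):
            raise ParameterError(f"thinning probability must be in [0, 1), got {self.p}")


@dataclass(frozen=True)
class CountSeries:
    """An ordered series of non-negative integer counts with sample-moment accessors."""

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 1 or arr.size < 2:
            raise DomainError("series must be 1-d with at least 2 observations")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise DomainError("series entries must be non-negative integers")
        object.__setattr__(self, "values", arr.astype(np.int64))

    @property
    def T(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def variance(self) -> float:
        """Sample variance with divisor T."""
        return float(np.var(self.values))

    @property
    def dispersion_index(self) -> float:
        return self.variance / self.mean

    def autocorrelation(self, lag: int = 1) -> float:
        """Sample ACF: sum_{t>lag}(X_t - Xbar)(X_{t-lag} - Xbar) / sum_t (X_t - Xbar)^2."""
        x = self.values.astype(float)
        xc = x - x.mean()
        denom = float(np.sum(xc**2))
        if denom == 0.0:
            raise DomainError("constant series has undefined autocorrelation")
        return float(np.sum(xc[lag:] * xc[:-lag]) / denom)


def binomial_thinning(x: int, p: float, seed=None) -> int:
    """One draw of p o x: a binomial(x, p) count of survivors."""
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"thinning probability must be in [0,1], got {p}")
    if x < 0 or x != int(x):
        raise DomainError(f"thinned count must be a non-negative integer, got {x}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return int(rng.binomial(int(x), p))


def simulate(
    model: INARModel,
    T: int,
    burn_in: int = 500,
    seed=None,
) -> CountSeries:
    """Simulate a stationary path of length T (after discarding burn_in steps).

    X_0 is drawn from the innovation law; geometric mixing at rate p makes the
    default burn-in of 500 ample for p <= 0.95.
    """
    if T < 1:
        raise DomainError(f"T must be >= 1, got {T}")
    if burn_in < 0:
        raise DomainError(f"burn_in must be >= 0, got {burn_in}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = T + burn_in
    eps = model.innovation.sample(total, rng)
    x = np.empty(total + 1, dtype=np.int64)
    x[0] = model.innovation.sample(1, rng)[0]
    p = model.p
    for t in range(total):
        x[t + 1] = rng.binomial(x[t], p) + eps[t]
    return CountSeries(x[burn_in + 1:])


def transition_logpmf(k, l, model: INARModel) -> np.ndarray | float:
    """log P(X_t = k | X_{t-1} = l), via log-sum-exp over the thinning count.

    P(k|l) = sum_{i=0}^{min(k,l)} C(l,i) p^i (1-p)^{l-i} * P(eps = k-i).
    """
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    l_arr = np.atleast_1d(np.asarray(l, dtype=np.int64))
    k_arr, l_arr = np.broadcast_arrays(k_arr, l_arr)
    if np.any(k_arr < 0) or np.any(l_arr < 0):
        raise DomainError("states must be non-negative integers")
    imax = np.minimum(k_arr, l_arr)
    M = int(imax.max())
    i = np.arange(M + 1)
    # (n_points, M+1) grids
    with np.errstate(divide="ignore"):
        lb = stats.binom.logpmf(i[None, :], l_arr[..., None], model.p)
        le = model.innovation.logpmf(k_arr[..., None] - i[None, :])
    terms = lb + le
    terms[i[None, :] > imax[..., None]] = -np.inf
    out = logsumexp(terms, axis=-1)
    if np.asarray(k).ndim == 0 and np.asarray(l).ndim == 0:
        return float(out[0])
    return out


def transition_probability(k, l, model: INARModel) -> np.ndarray | float:
    return np.exp(transition_logpmf(k, l, model))


def process_moments(model: INARModel) -> dict:
    """Exact stationary mean, variance and dispersion index of the process."""
    p = model.p
    mu_e = model.innovation.mean
    var_e = model.innovation.variance
    mean = mu_e / (1.0 - p)
    var = (p * mu_e + var_e) / (1.0 - p**2)
    return {"mean": mean, "variance": var, "dispersion_index": var / mean}


def pqx_process_moments(p: float, params: PQXParams) -> dict:
    """Closed-form INARPQX(1) stationary moments.

    mu_X   = (a+3) / (theta (a+1) (1-p))
    s2_X   = [a^2(t+tp+1) + 4a(t+tp+2) + 3(t+tp+1)] / [t^2 (a+1)^2 (1-p^2)]
    DI_X   = 1 + [a(a+8)+3] / [t (a+1)(a+3)(1+p)]

    These must coincide with :func:`process_moments` applied to a PQX
    innovation law; the identity is exercised in the test suite.
    """
    if not 0.0 <= p < 1.0:
        raise ParameterError(f"p must be in [0,1), got {p}")
    a, t = params.alpha, params.theta
    mean = (a + 3.0) / (t * (a + 1.0) * (1.0 - p))
    tp = t + t * p
    var = (
        a**2 * (tp + 1.0) + 4.0 * a * (tp + 2.0) + 3.0 * (tp + 1.0)
    ) / (t**2 * (a + 1.0) ** 2 * (1.0 - p**2))
    di = 1.0 + (a * (a + 8.0) + 3.0) / (t * (a + 1.0) * (a + 3.0) * (1.0 + p))
    return {"mean": mean, "variance": var, "dispersion_index": di}


def conditional_moments(x_prev, model: INARModel) -> dict:
    """One-step conditional mean and variance given X_{t-1} = x_prev.

    E[X_t | x]   = p x + mu_eps
    Var[X_t | x] = p (1-p) x + sigma2_eps

    For PQX innovations these are the closed forms with
    mu_eps = 2(a+3)/(theta(2a+2)) and sigma2_eps the PQX variance.
    """
    xp = np.asarray(x_prev, dtype=float)
    if np.any(xp < 0):
        raise DomainError("x_prev must be non-negative")
    p = model.p
    cm = p * xp + model.innovation.mean
    cv = p * (1.0 - p) * xp + model.innovation.variance
    if cm.ndim:
        return {"cond_mean": cm, "cond_variance": cv}
    return {"cond_mean": float(cm), "cond_variance": float(cv)}
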