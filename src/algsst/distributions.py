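"""Ex-Gaussian, Asymmetric Laplace and Asymmetric Laplace Gaussian distributions.

The three families used to model go reaction times (GORT) and their
trial-type differences in the stop signal task:

* ``ExG(mu, sigma, tau)`` — sum of an independent ``N(mu, sigma^2)`` and an
  ``Exp(tau)`` variate (``tau`` is the exponential *mean*, in ms).  The
  standard positively skewed reaction-time model.
* ``AL(alpha1, alpha2)`` — Asymmetric Laplace, the difference
  ``Exp(alpha2) - Exp(alpha1)`` of two independent exponentials.
* ``ALG(alpha1, alpha2, mu, sigma)`` — Asymmetric Laplace Gaussian (also
  known as the normal-Laplace distribution), the sum of an
  ``AL(alpha1, alpha2)`` and an independent ``N(mu, sigma^2)``.

If go reaction times after a go trial (type A) and after a stop trial
(type B) are independent and Ex-Gaussian, their difference
``GORT_B - GORT_A`` — the distributional index of proactive inhibition —
is exactly ``ALG(tau_A, tau_B, mu_B - mu_A, sqrt(sigma_A^2 + sigma_B^2))``;
see :func:`alg_from_components`.

All densities are evaluated in log space through a scaled complementary
error function (``erfcx``) / ``log_ndtr`` kernel so that extreme
``sigma/tau`` ratios and far-tail arguments neither overflow nor lose the
exponential tail.  Closed forms are validated elsewhere against
adaptive-quadrature convolution of the component densities.

Units: parameters and time arguments are milliseconds; densities are 1/ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Literal, Union

import numpy as np
from scipy import optimize, special
from scipy import stats as _sps

__all__ = [
    "ParameterError",
    "ExGParams",
    "ALParams",
    "ALGParams",
    "ShapeStats",
    "exg_pdf",
    "exg_logpdf",
    "exg_cdf",
    "exg_sf",
    "exg_mgf",
    "exg_cumulant",
    "exg_stats",
    "al_pdf",
    "al_cdf",
    "al_mgf",
    "al_cumulant",
    "al_stats",
    "alg_pdf",
    "alg_logpdf",
    "alg_cdf",
    "alg_sf",
    "alg_mgf",
    "alg_cumulant",
    "alg_stats",
    "classify_shape",
    "hazard",
    "sample",
    "alg_quantile",
    "alg_median",
    "alg_mode",
    "alg_from_components",
    "components_equivalent",
]

_LOG2 = math.log(2.0)
_SQRT2 = math.sqrt(2.0)


class ParameterError(ValueError):
    """Raised when distribution parameters are outside their domain."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ParameterError(message)


@dataclass(frozen=True)
class ExGParams:
    """Ex-Gaussian parameters: Gaussian location/scale and exponential mean (ms)."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        _require(all(math.isfinite(v) for v in (self.mu, self.sigma, self.tau)),
                 "ExG parameters must be finite")
        _require(self.sigma > 0, f"sigma must be > 0, got {self.sigma}")
        _require(self.tau > 0, f"tau must be > 0, got {self.tau}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExGParams":
        return cls(float(d["mu"]), float(d["sigma"]), float(d["tau"]))


@dataclass(frozen=True)
class ALParams:
    """Asymmetric Laplace parameters: left/right exponential means (ms).

    ``alpha1 = 0`` is accepted as the degenerate limit in which the left
    exponential vanishes and the distribution is plain ``Exp(alpha2)``.
    """

    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        _require(all(math.isfinite(v) for v in (self.alpha1, self.alpha2)),
                 "AL parameters must be finite")
        _require(self.alpha1 >= 0, f"alpha1 must be >= 0, got {self.alpha1}")
        _require(self.alpha2 > 0, f"alpha2 must be > 0, got {self.alpha2}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ALParams":
        return cls(float(d["alpha1"]), float(d["alpha2"]))


@dataclass(frozen=True)
class ALGParams:
    """Asymmetric Laplace Gaussian parameters (ms).

    ``alpha1``/``alpha2`` are the left/right exponential means of the
    Laplacian part, ``mu``/``sigma`` the Gaussian location and scale.
    ``alpha1 = 0`` degenerates exactly to ``ExG(mu, sigma, alpha2)``.
    """

    alpha1: float
    alpha2: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        _require(all(math.isfinite(v) for v in
                     (self.alpha1, self.alpha2, self.mu, self.sigma)),
                 "ALG parameters must be finite")
        _require(self.alpha1 >= 0, f"alpha1 must be >= 0, got {self.alpha1}")
        _require(self.alpha2 > 0, f"alpha2 must be > 0, got {self.alpha2}")
        _require(self.sigma > 0, f"sigma must be > 0, got {self.sigma}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ALGParams":
        return cls(float(d["alpha1"]), float(d["alpha2"]),
                   float(d["mu"]), float(d["sigma"]))


Params = Union[ExGParams, ALParams, ALGParams]
Family = Literal["ExG", "AL", "ALG"]

SkewClass = Literal["positive", "symmetric", "negative"]
KurtosisClass = Literal["leptokurtic", "mesokurtic", "platykurtic"]


@dataclass(frozen=True)
class ShapeStats:
    """Descriptive and shape statistics of an RT distribution.

    ``full_kurtosis`` is the classical kurtosis (3 for a Gaussian);
    ``excess_kurtosis`` is ``kappa_4 / kappa_2^2`` (0 for a Gaussian).
    Both conventions circulate for these families, so both are carried.
    """

    mean: float
    variance: float
    skewness: float
    excess_kurtosis: float
    full_kurtosis: float
    skew_class: SkewClass
    kurtosis_class: KurtosisClass

    def __post_init__(self) -> None:
        _require(self.variance > 0, "variance must be positive")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


def _classify_by_sign(value: float, scale: float, tol: float) -> int:
    """Sign of ``value`` with an absolute tolerance ``tol * scale``: -1, 0 or +1."""
    if abs(value) <= tol * max(scale, 1.0):
        return 0
    return 1 if value > 0 else -1


# ---------------------------------------------------------------------------
# Stable kernel shared by the ExG and ALG closed forms
# ---------------------------------------------------------------------------

def _log_tail_term(z: np.ndarray, r: float) -> np.ndarray:
    """``log[ exp(r^2/2 - z*r) * Phi(z - r) ]`` without overflow.

    ``z`` is the standardised time, ``r = sigma/tau`` the Gaussian-to-
    exponential scale ratio.  For ``z <= r`` the erfcx form
    ``exp(-z^2/2) * erfcx((r - z)/sqrt(2)) / 2`` is exact and bounded;
    for ``z > r`` the direct form with ``log_ndtr`` has no cancellation.
    """
    z = np.asarray(z, dtype=float)
    lo = np.minimum(z, r)          # safe inputs for the branch not taken
    hi = np.maximum(z, r)
    with np.errstate(over="ignore"):
        erfcx_branch = -0.5 * z * z + np.log(special.erfcx((r - lo) / _SQRT2)) - _LOG2
        direct_branch = 0.5 * r * r - hi * r + special.log_ndtr(hi - r)
    return np.where(z <= r, erfcx_branch, direct_branch)


# ---------------------------------------------------------------------------
# Ex-Gaussian
# ---------------------------------------------------------------------------

def exg_logpdf(t, p: ExGParams):
    """Log-density of ``ExG(mu, sigma, tau)`` at ``t`` (ms)."""
    z = (np.asarray(t, dtype=float) - p.mu) / p.sigma
    out = -math.log(p.tau) + _log_tail_term(z, p.sigma / p.tau)
    return out if out.ndim else float(out)


def exg_pdf(t, p: ExGParams):
    """Density of ``ExG(mu, sigma, tau)`` at ``t`` (1/ms)."""
    return np.exp(exg_logpdf(t, p))


def exg_cdf(t, p: ExGParams):
    """CDF of ``ExG(mu, sigma, tau)`` at ``t``."""
    z = (np.asarray(t, dtype=float) - p.mu) / p.sigma
    out = special.ndtr(z) - np.exp(_log_tail_term(z, p.sigma / p.tau))
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def exg_sf(t, p: ExGParams):
    """Survival function ``1 - CDF``; stable in the right tail."""
    z = (np.asarray(t, dtype=float) - p.mu) / p.sigma
    out = special.ndtr(-z) + np.exp(_log_tail_term(z, p.sigma / p.tau))
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def exg_mgf(t, p: ExGParams):
    """Moment generating function ``(1 - t*tau)^-1 exp(mu*t + sigma^2 t^2 / 2)``.

    Defined for ``t < 1/tau``.
    """
    t = float(t)
    if t >= 1.0 / p.tau:
        raise ParameterError(f"MGF of ExG requires t < 1/tau = {1.0 / p.tau}")
    return math.exp(p.mu * t + 0.5 * p.sigma ** 2 * t ** 2) / (1.0 - t * p.tau)


def exg_cumulant(n: int, p: ExGParams) -> float:
    """nth cumulant: ``(n-1)! tau^n`` plus ``mu`` (n=1) or ``sigma^2`` (n=2)."""
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ParameterError(f"cumulant order must be an integer >= 1, got {n}")
    k = math.factorial(n - 1) * p.tau ** n
    if n == 1:
        k += p.mu
    elif n == 2:
        k += p.sigma ** 2
    return k


def exg_stats(p: ExGParams, tol: float = 1e-9) -> ShapeStats:
    """Closed-form mean, variance, skewness and kurtosis of the Ex-Gaussian.

    mean = mu + tau, variance = sigma^2 + tau^2,
    skewness = 2 tau^3 / variance^{3/2},
    excess kurtosis = 6 tau^4 / variance^2 (full = excess + 3).
    """
    var = p.sigma ** 2 + p.tau ** 2
    skew = 2.0 * p.tau ** 3 / var ** 1.5
    excess = 6.0 * p.tau ** 4 / var ** 2
    sk = _classify_by_sign(skew, 1.0, tol)
    ku = _classify_by_sign(excess, 1.0, tol)
    return ShapeStats(
        mean=p.mu + p.tau,
        variance=var,
        skewness=skew,
        excess_kurtosis=excess,
        full_kurtosis=excess + 3.0,
        skew_class=("negative", "symmetric", "positive")[sk + 1],
        kurtosis_class=("platykurtic", "mesokurtic", "leptokurtic")[ku + 1],
    )


# ---------------------------------------------------------------------------
# Asymmetric Laplace
# ---------------------------------------------------------------------------

def al_pdf(t, p: ALParams):
    """Density of ``AL(alpha1, alpha2)``: two-sided exponential.

    ``exp(t/alpha1)/(alpha1+alpha2)`` for ``t < 0``,
    ``exp(-t/alpha2)/(alpha1+alpha2)`` for ``t >= 0``.  With ``alpha1 = 0``
    this is the ``Exp(alpha2)`` density (zero on the negative axis).
    """
    t = np.asarray(t, dtype=float)
    if p.alpha1 == 0.0:
        out = np.where(t >= 0, np.exp(-t / p.alpha2) / p.alpha2, 0.0)
    else:
        with np.errstate(over="ignore"):
            out = np.where(t < 0, np.exp(t / p.alpha1),
                           np.exp(-t / p.alpha2)) / (p.alpha1 + p.alpha2)
    return out if out.ndim else float(out)


def al_cdf(t, p: ALParams):
    """CDF of ``AL(alpha1, alpha2)``."""
    t = np.asarray(t, dtype=float)
    if p.alpha1 == 0.0:
        out = np.where(t >= 0, -np.expm1(-t / p.alpha2), 0.0)
    else:
        s = p.alpha1 + p.alpha2
        out = np.where(t < 0,
                       p.alpha1 * np.exp(np.minimum(t, 0.0) / p.alpha1) / s,
                       1.0 - p.alpha2 * np.exp(-np.maximum(t, 0.0) / p.alpha2) / s)
    return out if out.ndim else float(out)


def al_mgf(t, p: ALParams):
    """MGF ``[(1 + alpha1 t)(1 - alpha2 t)]^-1`` for ``-1/alpha1 < t < 1/alpha2``."""
    t = float(t)
    if t >= 1.0 / p.alpha2 or (p.alpha1 > 0 and t <= -1.0 / p.alpha1):
        raise ParameterError("t outside the MGF domain of AL")
    return 1.0 / ((1.0 + p.alpha1 * t) * (1.0 - p.alpha2 * t))


def al_cumulant(n: int, p: ALParams) -> float:
    """nth cumulant ``(n-1)! ((-alpha1)^n + alpha2^n)``."""
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ParameterError(f"cumulant order must be an integer >= 1, got {n}")
    return math.factorial(n - 1) * ((-p.alpha1) ** n + p.alpha2 ** n)


def al_stats(p: ALParams, tol: float = 1e-9) -> ShapeStats:
    """Closed-form moments of the Asymmetric Laplace.

    mean = alpha2 - alpha1, variance = alpha1^2 + alpha2^2,
    skewness = 2 (alpha2^3 - alpha1^3) / variance^{3/2},
    excess kurtosis = 6 (alpha1^4 + alpha2^4) / variance^2.
    """
    var = p.alpha1 ** 2 + p.alpha2 ** 2
    skew = 2.0 * (p.alpha2 ** 3 - p.alpha1 ** 3) / var ** 1.5
    excess = 6.0 * (p.alpha1 ** 4 + p.alpha2 ** 4) / var ** 2
    sk = _classify_by_sign(skew, 1.0, tol)
    ku = _classify_by_sign(excess, 1.0, tol)
    return ShapeStats(
        mean=p.alpha2 - p.alpha1,
        variance=var,
        skewness=skew,
        excess_kurtosis=excess,
        full_kurtosis=excess + 3.0,
        skew_class=("negative", "symmetric", "positive")[sk + 1],
        kurtosis_class=("platykurtic", "mesokurtic", "leptokurtic")[ku + 1],
    )


# ---------------------------------------------------------------------------
# Asymmetric Laplace Gaussian (normal-Laplace)
# ---------------------------------------------------------------------------

def _as_exg(p: ALGParams) -> ExGParams:
    return ExGParams(p.mu, p.sigma, p.alpha2)


def alg_logpdf(t, p: ALGParams):
    """Log-density of ``ALG(alpha1, alpha2, mu, sigma)``.

    Two exponential-times-Gaussian-tail terms, one per Laplacian tail:

    ``f(t) = [ exp(s^2/(2 a2^2) - (t-mu)/a2) Phi(z - s/a2)
             + exp(s^2/(2 a1^2) + (t-mu)/a1) Phi(-z - s/a1) ] / (a1 + a2)``

    with ``z = (t - mu)/sigma``.  Each term goes through the stable kernel,
    and the ``alpha1 = 0`` boundary reduces exactly to the Ex-Gaussian.
    """
    if p.alpha1 == 0.0:
        return exg_logpdf(t, _as_exg(p))
    z = (np.asarray(t, dtype=float) - p.mu) / p.sigma
    term_right = _log_tail_term(z, p.sigma / p.alpha2)
    term_left = _log_tail_term(-z, p.sigma / p.alpha1)
    out = np.logaddexp(term_right, term_left) - math.log(p.alpha1 + p.alpha2)
    return out if out.ndim else float(out)


def alg_pdf(t, p: ALGParams):
    """Density of the Asymmetric Laplace Gaussian (1/ms)."""
    return np.exp(alg_logpdf(t, p))


def alg_cdf(t, p: ALGParams):
    """CDF of the Asymmetric Laplace Gaussian.

    ``F(t) = Phi(z) - w2 T_right(t) + w1 T_left(t)`` with weights
    ``w_i = alpha_i / (alpha1 + alpha2)`` and the same two tail terms as
    the density.
    """
    if p.alpha1 == 0.0:
        return exg_cdf(t, _as_exg(p))
    z = (np.asarray(t, dtype=float) - p.mu) / p.sigma
    s = p.alpha1 + p.alpha2
    t_right = np.exp(_log_tail_term(z, p.sigma / p.alpha2))
    t_left = np.exp(_log_tail_term(-z, p.sigma / p.alpha1))
    out = special.ndtr(z) - (p.alpha2 / s) * t_right + (p.alpha1 / s) * t_left
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def alg_sf(t, p: ALGParams):
    """Survival function ``1 - F``; see :func:`_alg_log_sf` for the tail."""
    if p.alpha1 == 0.0:
        return exg_sf(t, _as_exg(p))
    z = (np.asarray(t, dtype=float) - p.mu) / p.sigma
    s = p.alpha1 + p.alpha2
    t_right = np.exp(_log_tail_term(z, p.sigma / p.alpha2))
    t_left = np.exp(_log_tail_term(-z, p.sigma / p.alpha1))
    out = special.ndtr(-z) + (p.alpha2 / s) * t_right - (p.alpha1 / s) * t_left
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def _alg_log_sf(t, p: ALGParams):
    """Log survival function, exact deep into the exponential right tail.

    Signed log-sum-exp of the three terms of ``1 - F``; where the signed
    sum degenerates numerically the result is marked -inf and the caller
    (the hazard) falls back to the ``Exp(alpha2)`` asymptote.
    """
    z = (np.asarray(t, dtype=float) - p.mu) / p.sigma
    s = p.alpha1 + p.alpha2
    log_right = _log_tail_term(z, p.sigma / p.alpha2) + math.log(p.alpha2 / s)
    a = special.log_ndtr(-z)
    if p.alpha1 == 0.0:
        out = np.logaddexp(a, log_right)
        return out if out.ndim else float(out)
    log_left = _log_tail_term(-z, p.sigma / p.alpha1) + math.log(p.alpha1 / s)
    stacked = np.stack([np.broadcast_to(a, np.shape(z)),
                        np.broadcast_to(log_right, np.shape(z)),
                        np.broadcast_to(log_left, np.shape(z))])
    signs = np.array([1.0, 1.0, -1.0]).reshape(3, *([1] * np.ndim(z)))
    out, sign = special.logsumexp(stacked, axis=0, b=signs, return_sign=True)
    out = np.where(sign > 0, out, -np.inf)
    return out if out.ndim else float(out)


def alg_mgf(t, p: ALGParams):
    """MGF ``exp(mu t + sigma^2 t^2/2) / [(1 + alpha1 t)(1 - alpha2 t)]``.

    Product of the AL and Gaussian MGFs on the common domain
    ``-1/alpha1 < t < 1/alpha2``.
    """
    t = float(t)
    if t >= 1.0 / p.alpha2 or (p.alpha1 > 0 and t <= -1.0 / p.alpha1):
        raise ParameterError("t outside the MGF domain of ALG")
    lap = 1.0 / ((1.0 + p.alpha1 * t) * (1.0 - p.alpha2 * t))
    return lap * math.exp(p.mu * t + 0.5 * p.sigma ** 2 * t ** 2)


def alg_cumulant(n: int, p: ALGParams) -> float:
    """nth cumulant ``(n-1)!((-alpha1)^n + alpha2^n)`` plus the Gaussian part.

    Cumulants of independent summands add, so this is the AL cumulant plus
    ``mu`` at order 1 and ``sigma^2`` at order 2.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ParameterError(f"cumulant order must be an integer >= 1, got {n}")
    k = math.factorial(n - 1) * ((-p.alpha1) ** n + p.alpha2 ** n)
    if n == 1:
        k += p.mu
    elif n == 2:
        k += p.sigma ** 2
    return k


def classify_shape(p: ALGParams, tol: float = 1e-9) -> tuple[SkewClass, KurtosisClass]:
    """Skewness and kurtosis classes of an ALG distribution.

    Skew: positive / symmetric / negative as ``alpha2`` >, =, < ``alpha1``.
    Kurtosis: leptokurtic / mesokurtic / platykurtic as
    ``sqrt(2 (alpha1^4 + alpha2^4)) - (alpha1^2 + alpha2^2)`` >, =, <
    ``sigma^2``.  With ``alpha1 = alpha2`` the left side is exactly zero,
    so an ALG with any Gaussian admixture is then platykurtic under this
    rule.  Equalities are decided with relative tolerance ``tol``.
    """
    scale = p.alpha1 + p.alpha2
    sk = _classify_by_sign(p.alpha2 - p.alpha1, scale, tol)
    lhs = math.sqrt(2.0 * (p.alpha1 ** 4 + p.alpha2 ** 4)) - (p.alpha1 ** 2 + p.alpha2 ** 2)
    ku = _classify_by_sign(lhs - p.sigma ** 2, max(abs(lhs), p.sigma ** 2), tol)
    skew_class = ("negative", "symmetric", "positive")[sk + 1]
    kurtosis_class = ("platykurtic", "mesokurtic", "leptokurtic")[ku + 1]
    return skew_class, kurtosis_class


def alg_stats(p: ALGParams, tol: float = 1e-9) -> ShapeStats:
    """Closed-form descriptive and shape statistics of the ALG.

    mean = alpha2 - alpha1 + mu,
    variance = alpha1^2 + alpha2^2 + sigma^2,
    skewness = 2 (alpha2^3 - alpha1^3) / variance^{3/2},
    excess kurtosis = 6 (alpha1^4 + alpha2^4) / variance^2.

    Classes follow :func:`classify_shape` (note the kurtosis class uses the
    dedicated inequality, not the sign of the excess kurtosis, which is
    strictly positive for any non-degenerate Laplacian part).
    """
    var = p.alpha1 ** 2 + p.alpha2 ** 2 + p.sigma ** 2
    skew = 2.0 * (p.alpha2 ** 3 - p.alpha1 ** 3) / var ** 1.5
    excess = 6.0 * (p.alpha1 ** 4 + p.alpha2 ** 4) / var ** 2
    skew_class, kurtosis_class = classify_shape(p, tol=tol)
    return ShapeStats(
        mean=p.alpha2 - p.alpha1 + p.mu,
        variance=var,
        skewness=skew,
        excess_kurtosis=excess,
        full_kurtosis=excess + 3.0,
        skew_class=skew_class,
        kurtosis_class=kurtosis_class,
    )


# ---------------------------------------------------------------------------
# Hazard functions
# ---------------------------------------------------------------------------

def _al_hazard(t, p: ALParams):
    t = np.asarray(t, dtype=float)
    if p.alpha1 == 0.0:
        return np.where(t >= 0, 1.0 / p.alpha2, 0.0)
    s = p.alpha1 + p.alpha2
    with np.errstate(over="ignore"):
        left = np.exp(np.minimum(t, 0.0) / p.alpha1)
    neg = left / (s - p.alpha1 * left)
    out = np.where(t >= 0, 1.0 / p.alpha2, neg)
    return out


def hazard(t, family: Family, params: Params):
    """Hazard rate ``f(t) / (1 - F(t))`` (1/ms) for ExG, AL or ALG.

    Evaluated as ``exp(log f - log S)`` with the log survival computed
    stably; deep in the exponential right tail, where the survival
    underflows even in log space, the exact ``Exp`` asymptote (``1/tau``
    for ExG, ``1/alpha2`` for AL/ALG) is returned instead of NaN.  The ExG
    and ALG hazards are non-decreasing (log-concave densities) and
    saturate at that asymptote.
    """
    t = np.asarray(t, dtype=float)
    if family == "AL":
        if not isinstance(params, ALParams):
            raise ParameterError("AL hazard requires ALParams")
        out = _al_hazard(t, params)
        return out if out.ndim else float(out)
    if family == "ExG":
        if not isinstance(params, ExGParams):
            raise ParameterError("ExG hazard requires ExGParams")
        z = (t - params.mu) / params.sigma
        log_f = exg_logpdf(t, params)
        log_s = np.logaddexp(special.log_ndtr(-z),
                             _log_tail_term(z, params.sigma / params.tau))
        asymptote = 1.0 / params.tau
    elif family == "ALG":
        if not isinstance(params, ALGParams):
            raise ParameterError("ALG hazard requires ALGParams")
        log_f = alg_logpdf(t, params)
        log_s = _alg_log_sf(t, params)
        asymptote = 1.0 / params.alpha2
    else:
        raise ParameterError(f"unknown family {family!r}")
    with np.errstate(invalid="ignore"):
        out = np.exp(np.asarray(log_f) - np.asarray(log_s))
    out = np.where(np.isfinite(out), out, asymptote)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample(family: Family, params: Params, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` variates by the defining Gaussian/exponential sums.

    ``seed`` may be an int or a ``numpy.random.Generator``.  ExG draws are
    ``normal + exponential``; AL draws are ``Exp(alpha2) - Exp(alpha1)``;
    ALG draws are the AL difference plus an independent Gaussian.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ParameterError(f"sample size must be a positive integer, got {n}")
    rng = np.random.default_rng(seed)
    if family == "ExG":
        if not isinstance(params, ExGParams):
            raise ParameterError("ExG sampling requires ExGParams")
        return rng.normal(params.mu, params.sigma, n) + rng.exponential(params.tau, n)
    if family == "AL":
        if not isinstance(params, ALParams):
            raise ParameterError("AL sampling requires ALParams")
        right = rng.exponential(params.alpha2, n)
        left = rng.exponential(params.alpha1, n) if params.alpha1 > 0 else 0.0
        return right - left
    if family == "ALG":
        if not isinstance(params, ALGParams):
            raise ParameterError("ALG sampling requires ALGParams")
        right = rng.exponential(params.alpha2, n)
        left = rng.exponential(params.alpha1, n) if params.alpha1 > 0 else 0.0
        return right - left + rng.normal(params.mu, params.sigma, n)
    raise ParameterError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Quantiles, median, mode
# ---------------------------------------------------------------------------

def _alg_sd(p: ALGParams) -> float:
    return math.sqrt(p.alpha1 ** 2 + p.alpha2 ** 2 + p.sigma ** 2)


def alg_quantile(q: float, p: ALGParams, xtol: float = 1e-9) -> float:
    """Quantile of the ALG by bracketed root finding on the CDF.

    The initial bracket is mean +- 12 sd, widened geometrically if the
    quantile falls outside (it cannot for any q in the double-precision
    range, but the expansion keeps the routine safe near 0 and 1).
    """
    q = float(q)
    if not 0.0 < q < 1.0:
        raise ParameterError(f"quantile level must be in (0, 1), got {q}")
    mean = p.alpha2 - p.alpha1 + p.mu
    sd = _alg_sd(p)
    lo, hi = mean - 12.0 * sd, mean + 12.0 * sd
    for _ in range(200):
        if alg_cdf(lo, p) < q:
            break
        lo = mean - 2.0 * (mean - lo)
    for _ in range(200):
        if alg_cdf(hi, p) > q:
            break
        hi = mean + 2.0 * (hi - mean)
    return float(optimize.brentq(lambda t: alg_cdf(t, p) - q, lo, hi, xtol=xtol))


def alg_median(p: ALGParams) -> float:
    """Median of the ALG (no closed form; numeric inversion at q = 0.5)."""
    return alg_quantile(0.5, p)


def alg_mode(p: ALGParams) -> float:
    """Mode of the ALG by line search on the (log-concave) log-density."""
    mean = p.alpha2 - p.alpha1 + p.mu
    sd = _alg_sd(p)
    res = optimize.minimize_scalar(
        lambda t: -alg_logpdf(t, p),
        bounds=(mean - 12.0 * sd, mean + 12.0 * sd),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# Plug-in construction and non-identifiability
# ---------------------------------------------------------------------------

def alg_from_components(theta_a: ExGParams, theta_b: ExGParams) -> ALGParams:
    """ALG law of the difference ``ExG_B - ExG_A`` of independent components.

    The MGF of ``ExG(mu_B, sigma_B, tau_B) - ExG(mu_A, sigma_A, tau_A)``
    factors into the MGF of ``AL(tau_A, tau_B)`` times that of
    ``N(mu_B - mu_A, sigma_A^2 + sigma_B^2)``, hence the difference is

    ``ALG(tau_A, tau_B, mu_B - mu_A, sqrt(sigma_A^2 + sigma_B^2))``.

    With type-A/type-B go-RT components this is the distribution of the
    proactive-inhibition index ``GORT_B - GORT_A``.
    """
    if not isinstance(theta_a, ExGParams) or not isinstance(theta_b, ExGParams):
        raise ParameterError("alg_from_components requires two ExGParams")
    return ALGParams(
        alpha1=theta_a.tau,
        alpha2=theta_b.tau,
        mu=theta_b.mu - theta_a.mu,
        sigma=math.hypot(theta_a.sigma, theta_b.sigma),
    )


def components_equivalent(pair1: tuple[ExGParams, ExGParams],
                          pair2: tuple[ExGParams, ExGParams],
                          rtol: float = 1e-12) -> bool:
    """True iff two component pairs induce the same ALG law.

    The map from ``(theta_A, theta_B)`` to the ALG depends only on
    ``(tau_A, tau_B, mu_B - mu_A, sigma_A^2 + sigma_B^2)``, so uncountably
    many component pairs are indistinguishable from the difference
    distribution alone.
    """
    p1 = alg_from_components(*pair1)
    p2 = alg_from_components(*pair2)
    vals1 = (p1.alpha1, p1.alpha2, p1.mu, p1.sigma)
    vals2 = (p2.alpha1, p2.alpha2, p2.mu, p2.sigma)
    return all(math.isclose(a, b, rel_tol=rtol, abs_tol=1e-12)
               for a, b in zip(vals1, vals2))


# Convenience: Kolmogorov-Smirnov helper used in validation work
def alg_ks_statistic(draws: np.ndarray, p: ALGParams):
    """Two-sided KS test of a sample against an ALG law (statistic, p-value)."""
    res = _sps.kstest(draws, lambda t: alg_cdf(t, p))
    return res.statistic, res.pvalue
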