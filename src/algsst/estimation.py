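"""Fitting Ex-Gaussian components and the Asymmetric Laplace Gaussian.

Two routes to a proactive-inhibition ALG model:

* **Plug-in** — fit an ExG to each cluster's go RTs (maximum likelihood,
  or posterior means from a per-participant Bayesian fit with uniform
  priors), then map the two component fits through
  :func:`algsst.distributions.alg_from_components`.
* **Direct** — form finite differences of the two unmatched GORT clusters
  (:func:`difference_gort`) and maximise the ALG likelihood on them.

The Bayesian fit is an adaptive random-walk Metropolis sampler on the ExG
likelihood under independent uniform priors, reporting pooled and
per-chain posterior means plus a split-chain dispersion diagnostic.  The
"ibpa_paper" profile runs 3 chains of 20,000 iterations with 5,000
burn-in; "ci_fast" is a scaled-down profile for quick runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import optimize

from .clustering import ClusteredGORT, ClusteringError
from .distributions import (
    ALGParams,
    ExGParams,
    ParameterError,
    alg_from_components,
    alg_logpdf,
    alg_stats,
    exg_logpdf,
)

__all__ = [
    "EstimationError",
    "PriorSpec",
    "FitResult",
    "MCMC_PROFILES",
    "fit_exg_mle",
    "fit_exg_bayes",
    "fit_alg_mle",
    "plug_in_alg",
    "difference_gort",
    "propagate_posterior",
]


class EstimationError(ValueError):
    """Raised when a fit is refused (too few observations, bad inputs)."""


MCMC_PROFILES = {
    "ibpa_paper": {"chains": 3, "burn_in": 5000, "iterations": 20000},
    "ci_fast": {"chains": 2, "burn_in": 500, "iterations": 2000},
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform prior bounds applied to each ExG parameter (ms)."""

    lower: float = 10.0
    upper: float = 2000.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise EstimationError("prior requires lower < upper")

    def contains(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta > self.lower) and np.all(theta < self.upper))


@dataclass
class FitResult:
    """A fitted distribution with its provenance and diagnostics."""

    family: str                      # "ExG" | "ALG"
    params: Union[ExGParams, ALGParams]
    log_likelihood: Optional[float]
    n_obs: int
    method: str                      # "mle" | "bayes_posterior_mean" | "plug_in"
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "method": self.method,
            "params": self.params.to_dict(),
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        cls_p = ExGParams if d["family"] == "ExG" else ALGParams
        return cls(
            family=d["family"],
            params=cls_p.from_dict(d["params"]),
            log_likelihood=d.get("log_likelihood"),
            n_obs=int(d["n_obs"]),
            method=d["method"],
            converged=bool(d.get("converged", True)),
            diagnostics=d.get("diagnostics", {}),
        )


# ---------------------------------------------------------------------------
# Ex-Gaussian maximum likelihood
# ---------------------------------------------------------------------------

def _exg_moment_init(rts: np.ndarray) -> ExGParams:
    """Method-of-moments start: tau from skewness, clipped into validity."""
    m, s = float(np.mean(rts)), float(np.std(rts, ddof=1))
    skew = float(np.mean(((rts - m) / s) ** 3)) if s > 0 else 0.0
    tau = s * (max(skew, 1e-3) / 2.0) ** (1.0 / 3.0)
    tau = min(max(tau, 1e-2 * s), 0.95 * s)
    sigma = math.sqrt(max(s ** 2 - tau ** 2, (0.05 * s) ** 2))
    return ExGParams(m - tau, sigma, tau)


def _exg_nll(x: np.ndarray, rts: np.ndarray) -> float:
    mu, log_sigma, log_tau = x
    p = ExGParams(mu, math.exp(log_sigma), math.exp(log_tau))
    return -float(np.sum(exg_logpdf(rts, p)))


def fit_exg_mle(rts, init: Optional[ExGParams] = None,
                min_n: int = 10) -> FitResult:
    """Maximum-likelihood ExG fit; sigma and tau optimised on log scale."""
    rts = np.asarray(rts, dtype=float)
    if rts.ndim != 1 or len(rts) < min_n:
        raise EstimationError(
            f"ExG fit needs at least {min_n} observations, got {len(rts)}")
    if not np.all(np.isfinite(rts)):
        raise EstimationError("RT vector contains non-finite values")
    p0 = init if init is not None else _exg_moment_init(rts)
    x0 = np.array([p0.mu, math.log(p0.sigma), math.log(p0.tau)])
    res = optimize.minimize(_exg_nll, x0, args=(rts,), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 4000})
    res2 = optimize.minimize(_exg_nll, res.x, args=(rts,), method="BFGS",
                             options={"gtol": 1e-6})
    best = res2 if res2.fun <= res.fun else res
    mu, log_sigma, log_tau = best.x
    params = ExGParams(float(mu), math.exp(log_sigma), math.exp(log_tau))
    return FitResult(
        family="ExG",
        params=params,
        log_likelihood=-float(best.fun),
        n_obs=len(rts),
        method="mle",
        converged=bool(res.success or res2.success),
        diagnostics={"iterations": int(res.nit) + int(res2.nit),
                     "small_sample": len(rts) < 30},
    )


# ---------------------------------------------------------------------------
# Ex-Gaussian Bayesian posterior means (adaptive random-walk Metropolis)
# ---------------------------------------------------------------------------

def _exg_loglik(theta: np.ndarray, rts: np.ndarray) -> float:
    p = ExGParams(float(theta[0]), float(theta[1]), float(theta[2]))
    return float(np.sum(exg_logpdf(rts, p)))


def _run_chain(rts, prior: PriorSpec, n_iter: int, burn_in: int,
               theta0: np.ndarray, rng: np.random.Generator):
    """One random-walk Metropolis chain; step scales adapt during burn-in."""
    theta = theta0.copy()
    ll = _exg_loglik(theta, rts)
    scales = np.maximum(0.05 * np.abs(theta), 1.0)
    kept = np.empty((n_iter - burn_in, 3))
    accepted = 0
    window_acc = np.zeros(3)
    window_n = 0
    for it in range(n_iter):
        for j in range(3):
            prop = theta.copy()
            prop[j] += rng.normal(0.0, scales[j])
            if not (prior.lower < prop[j] < prior.upper):
                continue
            ll_prop = _exg_loglik(prop, rts)
            if math.log(rng.random()) < ll_prop - ll:
                theta, ll = prop, ll_prop
                accepted += 1
                window_acc[j] += 1
        window_n += 1
        if it < burn_in and window_n == 50:
            rate = window_acc / window_n
            scales *= np.where(rate < 0.2, 0.6, np.where(rate > 0.5, 1.6, 1.0))
            window_acc[:] = 0
            window_n = 0
        if it >= burn_in:
            kept[it - burn_in] = theta
    return kept, accepted / (3 * n_iter)


def _split_chain_rhat(chains: list[np.ndarray]) -> np.ndarray:
    """Potential-scale-reduction diagnostic on split half-chains."""
    halves = []
    for c in chains:
        h = len(c) // 2
        halves.extend([c[:h], c[h:2 * h]])
    arr = np.stack(halves)             # (m, n, 3)
    m, n = arr.shape[0], arr.shape[1]
    means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / w)


def fit_exg_bayes(rts, prior: PriorSpec = PriorSpec(), chains: int = 3,
                  burn_in: int = 5000, iterations: int = 20000,
                  seed=None, min_n: int = 10) -> FitResult:
    """Posterior-mean ExG fit under uniform priors.

    ``iterations`` is the total chain length including ``burn_in``.
    Deterministic given ``seed``.  The result is flagged unconverged when
    any chain barely moves or the split-chain dispersion exceeds 1.2.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.ndim != 1 or len(rts) < min_n:
        raise EstimationError(
            f"ExG fit needs at least {min_n} observations, got {len(rts)}")
    if iterations <= burn_in:
        raise EstimationError("iterations must exceed burn_in")
    rng = np.random.default_rng(seed)
    init = _exg_moment_init(rts)
    base = np.clip(np.array([init.mu, init.sigma, init.tau]),
                   prior.lower * 1.05, prior.upper * 0.95)
    kept_chains = []
    acc_rates = []
    for _ in range(chains):
        theta0 = np.clip(base * rng.uniform(0.9, 1.1, size=3),
                         prior.lower * 1.01, prior.upper * 0.99)
        kept, acc = _run_chain(rts, prior, iterations, burn_in, theta0, rng)
        kept_chains.append(kept)
        acc_rates.append(acc)
    pooled = np.concatenate(kept_chains)
    post_mean = pooled.mean(axis=0)
    rhat = _split_chain_rhat(kept_chains)
    stuck = any(a < 0.02 for a in acc_rates)
    params = ExGParams(*post_mean)
    return FitResult(
        family="ExG",
        params=params,
        log_likelihood=_exg_loglik(post_mean, rts),
        n_obs=len(rts),
        method="bayes_posterior_mean",
        converged=not stuck and bool(np.all(rhat < 1.2)),
        diagnostics={
            "chains": chains,
            "burn_in": burn_in,
            "iterations": iterations,
            "acceptance_rates": [float(a) for a in acc_rates],
            "per_chain_means": [c.mean(axis=0).tolist() for c in kept_chains],
            "posterior_sd": pooled.std(axis=0, ddof=1).tolist(),
            "split_rhat": rhat.tolist(),
            "prior": {"lower": prior.lower, "upper": prior.upper},
            "at_prior_bound": bool(
                np.any(post_mean < prior.lower * 1.1)
                or np.any(post_mean > prior.upper * 0.9)),
        },
    )


def posterior_draws(fit: FitResult) -> np.ndarray:
    """Not retained by default; kept as API seam for custom samplers."""
    raise EstimationError("posterior draws were not stored in this FitResult")


# ---------------------------------------------------------------------------
# Plug-in ALG and direct ALG maximum likelihood
# ---------------------------------------------------------------------------

def plug_in_alg(fit_a: FitResult, fit_b: FitResult,
                force: bool = False) -> FitResult:
    """ALG for the proactive-inhibition difference from two ExG cluster fits."""
    for f, name in ((fit_a, "type A"), (fit_b, "type B")):
        if f.family != "ExG":
            raise EstimationError(f"{name} fit is not an ExG fit")
        if not f.converged and not force:
            raise EstimationError(
                f"{name} fit did not converge (pass force=True to override)")
    params = alg_from_components(fit_a.params, fit_b.params)
    return FitResult(
        family="ALG",
        params=params,
        log_likelihood=None,
        n_obs=min(fit_a.n_obs, fit_b.n_obs),
        method="plug_in",
        converged=fit_a.converged and fit_b.converged,
        diagnostics={"component_methods": [fit_a.method, fit_b.method]},
    )


def difference_gort(c: ClusteredGORT, pairing: str = "random_pairs",
                    seed=None) -> np.ndarray:
    """Finite difference sample ``GORT_B - GORT_A`` from unmatched clusters.

    ``all_pairs`` returns every b - a (|B| x |A| dependent values, whose
    mean equals the constant index exactly); ``random_pairs`` returns
    ``min(|A|, |B|)`` independent differences from a seeded random
    bijection without replacement.
    """
    if c.has_empty_cluster:
        raise ClusteringError("cannot difference an empty GORT cluster")
    if pairing == "all_pairs":
        return np.subtract.outer(c.gort_b, c.gort_a).ravel()
    if pairing == "random_pairs":
        rng = np.random.default_rng(seed)
        m = min(len(c.gort_a), len(c.gort_b))
        a = rng.permutation(c.gort_a)[:m]
        b = rng.permutation(c.gort_b)[:m]
        return b - a
    raise EstimationError(f"unknown pairing scheme {pairing!r}")


def _alg_cumulant_init(diffs: np.ndarray) -> ALGParams:
    """Start values solved from sample cumulants.

    ``alpha2`` from the third cumulant assuming the dominant right tail,
    ``alpha1`` from the fourth, the Gaussian absorbing the remainder.
    """
    m = float(np.mean(diffs))
    v = float(np.var(diffs, ddof=1))
    sd = math.sqrt(v)
    k3 = float(np.mean((diffs - m) ** 3))
    k4 = float(np.mean((diffs - m) ** 4)) - 3.0 * v ** 2
    a2 = max((abs(k3) / 2.0) ** (1.0 / 3.0), 0.05 * sd)
    a1 = max((max(k4 / 6.0 - a2 ** 4, 0.0)) ** 0.25, 0.05 * sd)
    if k3 < 0:
        a1, a2 = a2, a1
    a1 = min(a1, 0.9 * sd)
    a2 = min(a2, 0.9 * sd)
    sigma = math.sqrt(max(v - a1 ** 2 - a2 ** 2, (0.05 * sd) ** 2))
    return ALGParams(a1, a2, m - (a2 - a1), sigma)


def _alg_nll(x: np.ndarray, diffs: np.ndarray) -> float:
    log_a1, log_a2, mu, log_sigma = x
    p = ALGParams(math.exp(log_a1), math.exp(log_a2), mu, math.exp(log_sigma))
    return -float(np.sum(alg_logpdf(diffs, p)))


def fit_alg_mle(diffs, init: Optional[ALGParams] = None,
                min_n: int = 20) -> FitResult:
    """Direct maximum-likelihood ALG fit to differenced go RTs.

    Positive parameters are optimised on log scale, so the ExG boundary
    ``alpha1 -> 0`` is approached smoothly rather than failing; a fit
    sitting there is reported as the degenerate ExG case.  Weak
    identifiability (flat likelihood) is flagged via the condition number
    of the numerical information matrix.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 1 or len(diffs) < min_n:
        raise EstimationError(
            f"ALG fit needs at least {min_n} observations, got {len(diffs)}")
    if not np.all(np.isfinite(diffs)):
        raise EstimationError("difference vector contains non-finite values")
    p0 = init if init is not None else _alg_cumulant_init(diffs)
    a1_0 = max(p0.alpha1, 1e-6)
    x0 = np.array([math.log(a1_0), math.log(p0.alpha2), p0.mu,
                   math.log(p0.sigma)])
    res = optimize.minimize(_alg_nll, x0, args=(diffs,), method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-9,
                                     "maxiter": 8000, "maxfev": 12000})
    res2 = optimize.minimize(_alg_nll, res.x, args=(diffs,), method="BFGS",
                             options={"gtol": 1e-6})
    best = res2 if res2.fun <= res.fun else res
    log_a1, log_a2, mu, log_sigma = best.x
    params = ALGParams(math.exp(log_a1), math.exp(log_a2), float(mu),
                       math.exp(log_sigma))
    hess = _numerical_hessian(lambda x: _alg_nll(x, diffs), best.x)
    with np.errstate(all="ignore"):
        cond = float(np.linalg.cond(hess))
    weak = not np.isfinite(cond) or cond > 1e8
    return FitResult(
        family="ALG",
        params=params,
        log_likelihood=-float(best.fun),
        n_obs=len(diffs),
        method="mle",
        converged=bool(res.success or res2.success),
        diagnostics={
            "iterations": int(res.nit) + int(res2.nit),
            "information_condition_number": cond,
            "weak_identifiability": bool(weak),
            "near_exg_boundary": params.alpha1 < 1e-3 * params.alpha2,
        },
    )


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    hess = np.empty((n, n))
    f0 = f(x)
    steps = h * np.maximum(np.abs(x), 1.0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            val = (f(x + ei + ej) - f(x + ei - ej)
                   - f(x - ei + ej) + f(x - ei - ej)) / (4 * steps[i] * steps[j])
            hess[i, j] = hess[j, i] = val
    # fall back to a forward second difference on the diagonal if degenerate
    if not np.all(np.isfinite(hess)):
        hess = np.where(np.isfinite(hess), hess, 0.0)
        for i in range(n):
            if hess[i, i] == 0.0:
                ei = np.zeros(n); ei[i] = steps[i]
                hess[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
    return hess


# ---------------------------------------------------------------------------
# Posterior propagation through the plug-in map
# ---------------------------------------------------------------------------

def propagate_posterior(draws_a, draws_b, seed=None) -> dict:
    """Push posterior ExG draw pairs through the plug-in ALG construction.

    ``draws_a``/``draws_b`` are (n, 3) arrays of (mu, sigma, tau) draws.
    Unequal draw counts are reconciled by seeded resampling with
    replacement.  Returns posterior mean and central 95% interval for the
    ALG mean, sd, skewness and excess kurtosis (plus the raw statistic
    draws under ``"draws"``).
    """
    a = np.atleast_2d(np.asarray(draws_a, dtype=float))
    b = np.atleast_2d(np.asarray(draws_b, dtype=float))
    if a.shape[1] != 3 or b.shape[1] != 3:
        raise EstimationError("posterior draws must be (n, 3) arrays")
    n = max(len(a), len(b))
    rng = np.random.default_rng(seed)
    if len(a) != n:
        a = a[rng.integers(0, len(a), size=n)]
    if len(b) != n:
        b = b[rng.integers(0, len(b), size=n)]
    stats_draws = {"mean": [], "sd": [], "skewness": [], "excess_kurtosis": []}
    for ta, tb in zip(a, b):
        try:
            p = alg_from_components(ExGParams(*ta), ExGParams(*tb))
        except ParameterError:
            continue
        s = alg_stats(p)
        stats_draws["mean"].append(s.mean)
        stats_draws["sd"].append(s.sd)
        stats_draws["skewness"].append(s.skewness)
        stats_draws["excess_kurtosis"].append(s.excess_kurtosis)
    out = {}
    for key, vals in stats_draws.items():
        arr = np.asarray(vals)
        out[key] = {
            "mean": float(arr.mean()),
            "ci95": [float(np.percentile(arr, 2.5)),
                     float(np.percentile(arr, 97.5))],
        }
    out["draws"] = {k: np.asarray(v) for k, v in stats_draws.items()}
    return out
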