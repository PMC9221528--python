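"""Independent numerical oracles used by the tests.

These deliberately avoid the package's closed forms: densities are built
by adaptive-quadrature convolution of the component densities, and
moments by Monte-Carlo summation of raw Gaussian/exponential draws.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats

from algsst import ALGParams, ALParams


def al_pdf_direct(t, p: ALParams):
    """Two-sided exponential density, written independently of the package."""
    t = np.asarray(t, dtype=float)
    if p.alpha1 == 0:
        return np.where(t >= 0, np.exp(-t / p.alpha2) / p.alpha2, 0.0)
    return np.where(t < 0, np.exp(t / p.alpha1),
                    np.exp(-t / p.alpha2)) / (p.alpha1 + p.alpha2)


def al_cdf_direct(t, p: ALParams):
    t = np.asarray(t, dtype=float)
    s = p.alpha1 + p.alpha2
    return np.where(t < 0,
                    p.alpha1 * np.exp(np.minimum(t, 0) / max(p.alpha1, 1e-300)) / s,
                    1.0 - p.alpha2 * np.exp(-np.maximum(t, 0) / p.alpha2) / s)


def alg_pdf_quadrature(t: float, p: ALGParams) -> float:
    """Convolution of the AL density with the Gaussian by adaptive quadrature."""
    al = ALParams(p.alpha1, p.alpha2)
    f = lambda y: al_pdf_direct(t - y, al) * stats.norm.pdf(y, p.mu, p.sigma)
    lo, hi = p.mu - 13 * p.sigma, p.mu + 13 * p.sigma
    pts = [t] if lo < t < hi else None
    val, _ = integrate.quad(f, lo, hi, points=pts, limit=300, epsabs=1e-13,
                            epsrel=1e-11)
    return val


def alg_cdf_quadrature(t: float, p: ALGParams) -> float:
    """CDF by integrating the AL CDF against the Gaussian density."""
    al = ALParams(p.alpha1, p.alpha2)
    f = lambda y: al_cdf_direct(t - y, al) * stats.norm.pdf(y, p.mu, p.sigma)
    lo, hi = p.mu - 13 * p.sigma, p.mu + 13 * p.sigma
    pts = [t] if lo < t < hi else None
    val, _ = integrate.quad(f, lo, hi, points=pts, limit=300, epsabs=1e-13,
                            epsrel=1e-11)
    return val


def batched_moment_estimates(draws: np.ndarray, n_batches: int = 50):
    """Mean and standard error of mean/var/skew/excess-kurtosis by batching.

    Each statistic is computed within each batch; the batch mean and its
    standard error give a simple, assumption-free Monte-Carlo error bar.
    """
    batches = np.array_split(draws, n_batches)
    rows = []
    for b in batches:
        m = b.mean()
        c = b - m
        v = c.var(ddof=1)
        sd = np.sqrt(v)
        rows.append([m, v, np.mean(c ** 3) / sd ** 3,
                     np.mean(c ** 4) / v ** 2 - 3.0])
    arr = np.asarray(rows)
    return arr.mean(axis=0), arr.std(axis=0, ddof=1) / np.sqrt(n_batches)
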