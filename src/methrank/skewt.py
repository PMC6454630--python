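"""Fernandez-Steel skew Student-t and the logitSST distribution.

The skew-t density with skewness ``nu > 0`` and tail degrees of freedom
``tau > 2`` is

    f(z; nu, tau) = 2 / (nu + 1/nu) * [ f_t(z/nu; tau)  for z >= 0
                                        f_t(nu z; tau)  for z <  0 ],

a location-scale family via X = mu + sigma * Z.  ``nu = 1`` recovers the
symmetric Student-t; nu > 1 skews mass to the right.  Its CDF is piecewise
in the Student-t CDF and therefore has an exact closed-form inverse.

The logitSST distribution is the law of Y = 1/(1 + exp(-X)) on (0, 1); its
density is f_X(logit t) / (t (1 - t)).  It is the null family used for the
feature-level test statistic T.

All functions broadcast over numpy arrays; scalar in, scalar out.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, logit, stdtr, stdtrit

__all__ = [
    "sst_logpdf",
    "sst_cdf",
    "sst_ppf",
    "logitsst_logpdf",
    "logitsst_pdf",
    "logitsst_cdf",
    "logitsst_ppf",
    "logitsst_rvs",
]


def _t_logpdf(x, df):
    x = np.asarray(x, dtype=float)
    df = np.asarray(df, dtype=float)
    return (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - (df + 1.0) / 2.0 * np.log1p(x * x / df)
    )


def _check_shape(nu, tau):
    if np.any(np.asarray(nu) <= 0):
        raise ValueError("skewness nu must be positive")
    if np.any(np.asarray(tau) <= 2):
        raise ValueError("degrees of freedom tau must exceed 2")


def sst_logpdf(z, nu, tau):
    """Log-density of the standard (mu=0, sigma=1) Fernandez-Steel skew-t."""
    _check_shape(nu, tau)
    z = np.asarray(z, dtype=float)
    nu = np.asarray(nu, dtype=float)
    c = np.log(2.0) - np.log(nu + 1.0 / nu)
    arg = np.where(z >= 0, z / nu, z * nu)
    return c + _t_logpdf(arg, tau)


def sst_cdf(z, nu, tau):
    """CDF of the standard Fernandez-Steel skew-t (closed form)."""
    _check_shape(nu, tau)
    z = np.asarray(z, dtype=float)
    nu = np.asarray(nu, dtype=float)
    tau = np.asarray(tau, dtype=float)
    nu2 = nu * nu
    lower = 2.0 / (1.0 + nu2) * stdtr(tau, nu * np.minimum(z, 0.0))
    upper = (1.0 - nu2 + 2.0 * nu2 * stdtr(tau, np.maximum(z, 0.0) / nu)) / (
        1.0 + nu2
    )
    return np.where(z < 0, lower, upper)


def sst_ppf(u, nu, tau):
    """Exact inverse of ``sst_cdf`` for u in (0, 1)."""
    _check_shape(nu, tau)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("quantile argument must lie strictly in (0, 1)")
    nu = np.asarray(nu, dtype=float)
    tau = np.asarray(tau, dtype=float)
    nu2 = nu * nu
    split = 1.0 / (1.0 + nu2)
    u_lo = np.minimum(u, split)
    u_hi = np.maximum(u, split)
    z_lo = stdtrit(tau, u_lo * (1.0 + nu2) / 2.0) / nu
    z_hi = nu * stdtrit(tau, (u_hi * (1.0 + nu2) - 1.0 + nu2) / (2.0 * nu2))
    return np.where(u < split, z_lo, z_hi)


def _logit_z(t, mu, sigma):
    t = np.asarray(t, dtype=float)
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("logitSST support is the open interval (0, 1)")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    return (logit(t) - mu) / sigma, t


def logitsst_logpdf(t, mu, sigma, nu, tau):
    z, t = _logit_z(t, mu, sigma)
    return sst_logpdf(z, nu, tau) - np.log(sigma) - np.log(t * (1.0 - t))


def logitsst_pdf(t, mu, sigma, nu, tau):
    """Density of Y = logistic(mu + sigma Z), Z skew-t(nu, tau), on (0,1)."""
    return np.exp(logitsst_logpdf(t, mu, sigma, nu, tau))


def logitsst_cdf(t, mu, sigma, nu, tau):
    z, _ = _logit_z(t, mu, sigma)
    return sst_cdf(z, nu, tau)


def logitsst_ppf(u, mu, sigma, nu, tau):
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    return expit(mu + sigma * sst_ppf(u, nu, tau))


def logitsst_rvs(rng: np.random.Generator, mu, sigma, nu, tau, size=None):
    """Draw logitSST variates by inverse-CDF sampling."""
    u = rng.uniform(
        np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0), size=size
    )
    return logitsst_ppf(u, mu, sigma, nu, tau)
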