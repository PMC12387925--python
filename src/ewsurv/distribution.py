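"""Exponentiated Weibull lifetime distribution.

The exponentiated Weibull is a three-parameter lifetime family obtained by
raising the Weibull CDF to a positive power:

    F(t) = [1 - exp(-(t / sigma)**theta)] ** alpha,   t >= 0

with exponentiation shape ``alpha > 0``, Weibull shape ``theta > 0`` and
scale ``sigma > 0`` (here in days).  Unlike the plain Weibull it admits
unimodal and bathtub-shaped hazards, which makes it a flexible parametric
model for post-infection mortality curves.  At ``alpha == 1`` every function
below reduces exactly to the two-parameter Weibull, and additionally at
``theta == 1`` to the exponential.

All functions are vectorised over ``t`` (and ``q``) via numpy broadcasting
and accept either an :class:`ExpWeibullParams` or the three scalars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExpWeibullParams",
    "ew_cdf",
    "ew_sf",
    "ew_pdf",
    "ew_logpdf",
    "ew_hazard",
    "ew_quantile",
    "median_residual_lifetime",
]


@dataclass(frozen=True)
class ExpWeibullParams:
    """Parameter triple (alpha, theta, sigma), all strictly positive.

    alpha : exponentiation shape (unitless)
    theta : Weibull shape (unitless)
    sigma : scale (days)
    """

    alpha: float
    theta: float
    sigma: float

    def __post_init__(self) -> None:
        for name in ("alpha", "theta", "sigma"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(
                    f"{name} must be a positive finite number, got {value!r}"
                )


def _unpack(p, alpha, theta, sigma):
    if p is not None:
        return p.alpha, p.theta, p.sigma
    q = ExpWeibullParams(alpha, theta, sigma)  # validates
    return q.alpha, q.theta, q.sigma


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    return t


def ew_cdf(t, p: ExpWeibullParams | None = None, *, alpha=None, theta=None, sigma=None):
    """Cumulative distribution function F(t) = [1 - exp(-(t/sigma)^theta)]^alpha."""
    a, th, sc = _unpack(p, alpha, theta, sigma)
    t = _check_t(t)
    z = (t / sc) ** th
    return (-np.expm1(-z)) ** a


def ew_sf(t, p: ExpWeibullParams | None = None, *, alpha=None, theta=None, sigma=None):
    """Survival function S(t) = 1 - F(t), computed in log space for stability."""
    a, th, sc = _unpack(p, alpha, theta, sigma)
    t = _check_t(t)
    z = (t / sc) ** th
    with np.errstate(divide="ignore"):
        log_f = a * np.log(-np.expm1(-z))  # log F(t); -inf at t == 0
    return -np.expm1(log_f)


def ew_logpdf(t, p: ExpWeibullParams | None = None, *, alpha=None, theta=None, sigma=None):
    """Log density.  Returns -inf where the density is zero (including t=0 when
    alpha*theta > 1)."""
    a, th, sc = _unpack(p, alpha, theta, sigma)
    t = _check_t(t)
    tt = np.where(t > 0, t, np.nan)  # t=0 handled separately below
    u = tt / sc
    z = u**th
    with np.errstate(divide="ignore", invalid="ignore"):
        log_base = np.log(-np.expm1(-z))  # log(1 - e^{-z}) < 0
        out = (
            math.log(a)
            + math.log(th)
            - math.log(sc)
            + (th - 1.0) * np.log(u)
            - z
            + (a - 1.0) * log_base
        )
    # Boundary: f(t) ~ (a*th/sc) * (t/sc)^(a*th - 1) as t -> 0.
    if np.any(t == 0):
        prod = a * th
        if prod > 1:
            limit = -np.inf
        elif prod == 1:
            limit = math.log(a * th / sc)
        else:
            limit = np.inf
        out = np.where(t == 0, limit, out)
    return out


def ew_pdf(t, p: ExpWeibullParams | None = None, *, alpha=None, theta=None, sigma=None):
    """Probability density function (per day)."""
    return np.exp(ew_logpdf(t, p, alpha=alpha, theta=theta, sigma=sigma))


def ew_hazard(t, p: ExpWeibullParams | None = None, *, alpha=None, theta=None, sigma=None):
    """Hazard rate h(t) = f(t) / S(t) (per day)."""
    a, th, sc = _unpack(p, alpha, theta, sigma)
    t = _check_t(t)
    logf = ew_logpdf(t, alpha=a, theta=th, sigma=sc)
    sf = ew_sf(t, alpha=a, theta=th, sigma=sc)
    with np.errstate(divide="ignore", over="ignore"):
        return np.exp(logf) / sf


def ew_quantile(q, p: ExpWeibullParams | None = None, *, alpha=None, theta=None, sigma=None):
    """Quantile function, closed form:

        t(q) = sigma * (-log(1 - q**(1/alpha)))**(1/theta)

    Accepts q in [0, 1); q = 0 maps to 0.
    """
    a, th, sc = _unpack(p, alpha, theta, sigma)
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("quantile level q must lie in [0, 1)")
    with np.errstate(divide="ignore"):
        inner = -np.log1p(-(q ** (1.0 / a)))
    return sc * inner ** (1.0 / th)


def median_residual_lifetime(
    t0, p: ExpWeibullParams | None = None, *, alpha=None, theta=None, sigma=None
):
    """Median residual lifetime at age ``t0``.

    The time from ``t0`` until half of the individuals alive at ``t0`` have
    died: the solution m of S(t0 + m) = S(t0) / 2, computed in closed form by
    inverting the CDF at 1 - S(t0)/2.  Requires S(t0) > 0.
    """
    a, th, sc = _unpack(p, alpha, theta, sigma)
    t0 = _check_t(t0)
    s0 = ew_sf(t0, alpha=a, theta=th, sigma=sc)
    if np.any(s0 <= 0) or np.any(~np.isfinite(s0)):
        raise ValueError(
            "median residual lifetime undefined: survival is numerically zero at t0"
        )
    target = 1.0 - s0 / 2.0
    return ew_quantile(target, alpha=a, theta=th, sigma=sc) - t0
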