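"""Biphasic generalized logistic growth model for cell-count time series.

The mean cell density ``n`` days after inoculation is modelled as the sum of
two logistic phases on top of a unit floor:

    mu(n) = 1 + (K1 - 1) / (1 + exp(-B1 (n - M1)))
              + w * k / (1 + exp(-B2 (n - M1 - m)))

where ``K1`` is the asymptote of the first phase, ``k`` the additional
asymptotic density contributed by the second phase, ``B1``/``B2`` the logistic
rates, ``M1`` the day of maximum growth of the first phase, ``m`` the extra
days to the second phase's maximum growth, and ``w`` a binary indicator that
switches the second phase on (biphasic, w=1) or off (monophasic, w=0).

Observed densities ``D`` (integer counts on the 10^4 cells/ml scale) are
overdispersed Poisson: D ~ Poisson(mu * rho) with rho ~ Gamma(alpha, alpha),
so that marginally D is negative binomial with mean mu and shape alpha
(variance mu + mu^2 / alpha).

Everything here is a pure function of a :class:`GrowthParams` draw; sampling
lives in :mod:`symgrowth.inference`.
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from dataclasses import dataclass, replace
from typing import Union

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "PRIOR_BOUNDS",
    "PARAM_NAMES",
    "GrowthParams",
    "DerivedQuantities",
    "Observation",
    "expected_density",
    "growth_rate",
    "derived_quantities",
    "log_likelihood_conditional",
    "log_likelihood_marginal",
    "log_prior",
    "override_prior_bounds",
]

#: Uniform prior supports for the continuous curve parameters.
PRIOR_BOUNDS: dict[str, tuple[float, float]] = {
    "K1": (1.0, 800.0),
    "k": (1.0, 500.0),
    "B1": (0.1, 1.0),
    "B2": (0.1, 1.0),
    "M1": (2.0, 40.0),
    "m": (2.0, 40.0),
}

#: Log-scale standard deviation of the Lognormal prior on alpha
#: (precision tau = 1e-4 on the log scale).
ALPHA_LOG_SD = 100.0

#: Canonical parameter ordering used throughout the package.
PARAM_NAMES = ("K1", "k", "B1", "B2", "M1", "m", "w", "alpha")


@dataclass(frozen=True)
class GrowthParams:
    """One draw of the growth-model parameter vector.

    Units: densities in 10^4 cells/ml, rates in 1/day, times in days.
    """

    K1: float
    k: float
    B1: float
    B2: float
    M1: float
    m: float
    w: int
    alpha: float

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field if invalid."""
        for name, (lo, hi) in PRIOR_BOUNDS.items():
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} is not finite: {v!r}")
            if not lo <= v <= hi:
                raise ValueError(
                    f"parameter {name}={v} outside prior support [{lo}, {hi}]"
                )
        if self.w not in (0, 1):
            raise ValueError(f"parameter w={self.w!r} must be 0 or 1")
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"parameter alpha={self.alpha!r} must be finite and > 0")

    def in_support(self) -> bool:
        try:
            self.validate()
        except ValueError:
            return False
        return True

    def replace(self, **kwargs) -> "GrowthParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DerivedQuantities:
    """Per-draw growth quantities derived from :class:`GrowthParams`."""

    K2: float      #: K1 + k, asymptote of the full biphasic curve
    K_max: float   #: realized maximum asymptotic density (K1 or K2 per w)
    M2: float      #: M1 + m, day of the second phase's maximum growth
    R_M1: float    #: growth rate of the mean curve at day M1
    R_M2: float    #: growth rate of the mean curve at day M2
    R_max: float   #: maximum rate of growth per the switching rule
    M_Rmax: float  #: day at maximum growth per the switching rule


@dataclass(frozen=True)
class Observation:
    """A single hemocytometer count.

    ``density`` is an integer on the 10^4 cells/ml scale (Poisson support);
    ``replicate`` is an opaque tube/aliquot label.
    """

    day: float
    density: int
    replicate: str = ""

    def validate(self) -> None:
        if not math.isfinite(self.day) or self.day < 0:
            raise ValueError(f"observation day={self.day!r} must be finite and >= 0")
        d = self.density
        if d < 0 or d != int(d):
            raise ValueError(
                f"observation density={d!r} must be a non-negative integer"
            )


def _check_day(day) -> np.ndarray:
    day = np.asarray(day, dtype=float)
    if not np.all(np.isfinite(day)):
        raise ValueError("day is not finite")
    return day


def _mu_terms(params: GrowthParams, day: np.ndarray):
    """The two normalized logistic terms sigma1, sigma2 of the mean curve."""
    s1 = expit(params.B1 * (day - params.M1))
    s2 = expit(params.B2 * (day - params.M1 - params.m))
    return s1, s2


def expected_density(params: GrowthParams, day) -> Union[float, np.ndarray]:
    """Mean cell density mu(day), in 10^4 cells/ml.

    Strictly increasing in ``day``, bounded below by 1 and above by
    ``1 + (K1 - 1) + w*k`` (the floor plus the phase asymptotes); the
    supremum over day equals ``K1 + w*k``.
    """
    params.validate()
    day = _check_day(day)
    s1, s2 = _mu_terms(params, day)
    mu = 1.0 + (params.K1 - 1.0) * s1 + params.w * params.k * s2
    return float(mu) if mu.ndim == 0 else mu


def growth_rate(params: GrowthParams, day) -> Union[float, np.ndarray]:
    """First derivative of the mean curve, d(mu)/d(day).

    Includes both phases' contributions (the second scaled by ``w``), so it
    is the slope of the full mean trajectory, not of one phase alone.
    """
    params.validate()
    day = _check_day(day)
    s1, s2 = _mu_terms(params, day)
    rate = (params.K1 - 1.0) * params.B1 * s1 * (1.0 - s1)
    rate = rate + params.w * params.k * params.B2 * s2 * (1.0 - s2)
    return float(rate) if rate.ndim == 0 else rate


def derived_quantities(params: GrowthParams) -> DerivedQuantities:
    """Derived growth quantities for one parameter draw.

    ``K_max`` is K1 for a monophasic draw and K2 = K1 + k for a biphasic
    one.  ``R_M1``/``R_M2`` evaluate the full-curve derivative at M1 and
    M2 = M1 + m.  ``R_max`` is R_M1 for monophasic draws and the larger of
    R_M1/R_M2 for biphasic draws; ``M_Rmax`` is M1 when w = 0 or B1 > B2
    (ties resolved toward the first phase), otherwise M2.
    """
    params.validate()
    K2 = params.K1 + params.k
    M2 = params.M1 + params.m
    r_m1 = growth_rate(params, params.M1)
    r_m2 = growth_rate(params, M2)
    if params.w == 0:
        return DerivedQuantities(
            K2=K2, K_max=params.K1, M2=M2,
            R_M1=r_m1, R_M2=r_m2, R_max=r_m1, M_Rmax=params.M1,
        )
    r_max = max(r_m1, r_m2)
    m_rmax = params.M1 if params.B1 >= params.B2 else M2
    return DerivedQuantities(
        K2=K2, K_max=K2, M2=M2,
        R_M1=r_m1, R_M2=r_m2, R_max=r_max, M_Rmax=m_rmax,
    )


def _check_density(density) -> np.ndarray:
    d = np.asarray(density)
    if np.any(d < 0) or not np.all(np.equal(np.mod(d, 1), 0)):
        raise ValueError("density must be a non-negative integer count")
    return d.astype(float)


def log_likelihood_conditional(params: GrowthParams, rho: float, obs: Observation) -> float:
    """Log Poisson pmf of the count given the overdispersion draw rho.

    D ~ Poisson(mu(day) * rho).
    """
    if not (math.isfinite(rho) and rho > 0):
        raise ValueError(f"rho={rho!r} must be finite and > 0")
    obs.validate()
    d = float(obs.density)
    lam = expected_density(params, obs.day) * rho
    return d * math.log(lam) - lam - float(gammaln(d + 1.0))


_GAMMALN_RATIO_STIRLING = 1e6


def gammaln_ratio(d, alpha: float):
    """Stable ``gammaln(d + alpha) - gammaln(alpha) - d * log(alpha)``.

    The three terms each grow like ``alpha * log(alpha)`` while their sum is
    O(d^2 / alpha); beyond ``alpha ~ 1e8`` the direct difference is pure
    cancellation noise (and overflows near ``alpha ~ 1e300``), which lets an
    MCMC chain random-walk into garbage likelihood regions.  For large alpha
    the difference is evaluated from Stirling's series instead, whose
    remainder is O(1/alpha^3) at the switch point.
    """
    d = np.asarray(d, dtype=float)
    if alpha < _GAMMALN_RATIO_STIRLING:
        return gammaln(d + alpha) - gammaln(alpha) - d * math.log(alpha)
    t = np.log1p(d / alpha)
    return (alpha + d - 0.5) * t - d + 1.0 / (12.0 * (alpha + d)) - 1.0 / (12.0 * alpha)


def log_likelihood_marginal(params: GrowthParams, obs: Observation) -> float:
    """Log negative-binomial pmf with rho ~ Gamma(alpha, alpha) integrated out.

    The marginal has mean mu and variance mu + mu^2 / alpha.
    """
    obs.validate()
    d = float(obs.density)
    mu = expected_density(params, obs.day)
    a = params.alpha
    return float(
        gammaln_ratio(d, a) - gammaln(d + 1.0)
        + d * math.log(mu)
        - (d + a) * math.log1p(mu / a)
    )


_LOG_BERN_HALF = math.log(0.5)


@contextmanager
def override_prior_bounds(**bounds):
    """Temporarily replace uniform prior supports (e.g. ``K1=(1, 400)``).

    Affects every function that consults :data:`PRIOR_BOUNDS`, including the
    sampler; restored on exit even on error.
    """
    saved = dict(PRIOR_BOUNDS)
    try:
        for name, (lo, hi) in bounds.items():
            if name not in PRIOR_BOUNDS:
                raise ValueError(f"unknown prior-bound name {name!r}")
            lo, hi = float(lo), float(hi)
            if not lo < hi:
                raise ValueError(f"prior bound for {name} must have lower < upper")
            PRIOR_BOUNDS[name] = (lo, hi)
        yield
    finally:
        PRIOR_BOUNDS.clear()
        PRIOR_BOUNDS.update(saved)


def log_prior(params: GrowthParams) -> float:
    """Joint log prior density of one parameter vector.

    Uniform priors on the curve parameters, Bernoulli(0.5) on w, and a
    Lognormal(0, sd=100 on the log scale) prior on alpha.  Returns -inf
    outside any uniform support (a legal value, not an error).
    """
    for name, (lo, hi) in PRIOR_BOUNDS.items():
        v = getattr(params, name)
        if not (lo <= v <= hi):
            return -math.inf
    if params.w not in (0, 1):
        return -math.inf
    if not (params.alpha > 0 and math.isfinite(params.alpha)):
        return -math.inf
    la = math.log(params.alpha)
    log_alpha_prior = (
        -la - math.log(ALPHA_LOG_SD * math.sqrt(2.0 * math.pi))
        - 0.5 * (la / ALPHA_LOG_SD) ** 2
    )
    log_uniform = sum(-math.log(hi - lo) for lo, hi in PRIOR_BOUNDS.values())
    return log_uniform + _LOG_BERN_HALF + log_alpha_prior
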