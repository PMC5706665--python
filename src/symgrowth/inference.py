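"""Posterior sampling for the biphasic growth model.

A Metropolis-within-Gibbs sampler targets the joint posterior over
``(K1, k, B1, B2, M1, m, w, alpha)`` given one strain x treatment count
series.  The overdispersion draw rho is integrated out analytically, so each
count contributes a negative-binomial likelihood term with mean mu(day) and
shape alpha.

Model switching uses the binary indicator ``w`` a la Carlin & Chib: ``w`` is
Gibbs-updated from its exact full conditional (Bernoulli with odds equal to
the likelihood ratio of the biphasic vs monophasic mean curve; prior odds 1),
and while ``w = 0`` the second-phase parameters ``(k, B2, m)`` carry no
likelihood information and are refreshed from their priors each sweep, so the
chain mixes over the pseudo-prior.

Continuous parameters move by Gaussian random-walk Metropolis: the curve
parameters on their natural scale, alpha on the log scale.  Proposal scales
adapt toward a 20-45% acceptance rate during the adaptation and burn-in
phases and are frozen before the sampling phase, which preserves detailed
balance for the retained draws.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .growth_model import (
    ALPHA_LOG_SD,
    PARAM_NAMES,
    PRIOR_BOUNDS,
    GrowthParams,
    gammaln_ratio,
)

__all__ = [
    "MCMCConfig",
    "FULL_PROTOCOL",
    "PosteriorSamples",
    "sample_prior",
    "run_mcmc",
    "psrf",
    "psrf_report",
    "PSRF_BOUND",
]

logger = logging.getLogger("symgrowth.inference")

#: Convergence bound used in diagnostic reports (PSRF above this triggers a
#: warning).
PSRF_BOUND = 1.08

_CONTINUOUS = ("K1", "k", "B1", "B2", "M1", "m", "alpha")
_SECOND_PHASE = ("k", "B2", "m")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout and tuning knobs for :func:`run_mcmc`.

    Defaults are a desk-scale protocol; :data:`FULL_PROTOCOL` holds the
    full-scale production layout (10 chains x 1e6 burn-in + 1e6 sampling, thin 1,000).
    """

    n_chains: int = 4
    n_adapt: int = 1_000
    n_burnin: int = 20_000
    n_samples: int = 20_000
    thin: int = 20
    seed: int = 0
    proposal_scales: Optional[Mapping[str, float]] = None

    def validate(self) -> None:
        for name in ("n_chains", "n_adapt", "n_burnin", "n_samples", "thin"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"MCMCConfig.{name} must be a positive integer, got {v!r}")
        if self.n_samples % self.thin != 0:
            raise ValueError(
                f"thin={self.thin} must divide n_samples={self.n_samples}"
            )
        if self.proposal_scales is not None:
            for key, val in self.proposal_scales.items():
                if key not in _CONTINUOUS:
                    raise ValueError(f"unknown proposal-scale key {key!r}")
                if not val > 0:
                    raise ValueError(f"proposal scale for {key} must be > 0")

    @property
    def draws_per_chain(self) -> int:
        return self.n_samples // self.thin


#: Full-scale protocol for production runs (hours of compute; use deliberately).
FULL_PROTOCOL = MCMCConfig(
    n_chains=10, n_adapt=1_000, n_burnin=1_000_000, n_samples=1_000_000, thin=1_000
)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, one matrix (n_chains, n_kept) per parameter."""

    draws: dict[str, np.ndarray]
    config: MCMCConfig
    data_digest: str = ""
    strain: str = ""
    treatment: str = ""
    acceptance_rates: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_total(self) -> int:
        mat = next(iter(self.draws.values()))
        return int(mat.shape[0] * mat.shape[1])

    def pooled(self, name: str) -> np.ndarray:
        """All chains' retained draws of one parameter, concatenated."""
        return self.draws[name].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per retained draw with chain/iteration ids."""
        mat = next(iter(self.draws.values()))
        n_chains, n_kept = mat.shape
        out = pd.DataFrame(
            {
                "chain": np.repeat(np.arange(n_chains), n_kept),
                "iteration": np.tile(np.arange(n_kept), n_chains),
            }
        )
        for name in PARAM_NAMES:
            out[name] = self.draws[name].reshape(-1)
        return out

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: Optional[MCMCConfig] = None, **meta
    ) -> "PosteriorSamples":
        chains = np.sort(df["chain"].unique())
        draws: dict[str, np.ndarray] = {}
        per_chain = [df[df["chain"] == c].sort_values("iteration") for c in chains]
        lengths = {len(p) for p in per_chain}
        if len(lengths) != 1:
            raise ValueError("chains have unequal numbers of retained draws")
        for name in PARAM_NAMES:
            draws[name] = np.vstack([p[name].to_numpy(float) for p in per_chain])
        if config is None:
            n_kept = lengths.pop()
            config = MCMCConfig(
                n_chains=len(chains), n_samples=n_kept, thin=1, n_burnin=1, n_adapt=1
            )
        return cls(draws=draws, config=config, **meta)

    @classmethod
    def read_csv(cls, path, **meta) -> "PosteriorSamples":
        return cls.from_dataframe(pd.read_csv(path), **meta)


def sample_prior(seed) -> GrowthParams:
    """One joint prior draw; ``seed`` is an integer or a numpy Generator."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = {
        name: rng.uniform(lo, hi) for name, (lo, hi) in PRIOR_BOUNDS.items()
    }
    w = int(rng.random() < 0.5)
    alpha = math.exp(rng.normal(0.0, ALPHA_LOG_SD))
    return GrowthParams(w=w, alpha=alpha, **vals)


# ---------------------------------------------------------------------------
# Likelihood machinery (sufficient statistics per counting day)
# ---------------------------------------------------------------------------

class _Series:
    """Per-day sufficient statistics for the negative-binomial likelihood.

    log L = A(alpha) + sum_d [ S_d ln mu_d - (S_d + n_d alpha) ln(alpha + mu_d) ]
    with S_d the summed counts and n_d the number of counts on day d, and
    A(alpha) collecting all terms that do not involve the mean curve.
    """

    def __init__(self, days: np.ndarray, counts: np.ndarray):
        days = np.asarray(days, dtype=float)
        counts = np.asarray(counts)
        if counts.size == 0:
            raise ValueError("empty observation series")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)) or np.any(counts < 0):
                raise ValueError("densities must be non-negative integers")
        self.counts = counts.astype(float)
        self.udays, inverse = np.unique(days, return_inverse=True)
        self.n_d = np.bincount(inverse).astype(float)
        self.sum_d = np.bincount(inverse, weights=self.counts)
        self.n = float(self.counts.size)
        self._gammaln_d1 = float(np.sum(gammaln(self.counts + 1.0)))
        if not np.any(self.counts > 0):
            logger.warning(
                "all observed densities are zero; the likelihood degenerates "
                "toward the lower prior bound of K1"
            )

    def alpha_const(self, alpha: float) -> float:
        # gammaln_ratio folds the alpha*log(alpha) normalization into the
        # gammaln difference so no term here grows without bound in alpha
        return float(np.sum(gammaln_ratio(self.counts, alpha))) - self._gammaln_d1

    def curve_part(self, mu_d: np.ndarray, alpha: float) -> float:
        # log1p keeps the Poisson limit (alpha -> inf) exact to rounding
        return float(
            np.sum(
                self.sum_d * np.log(mu_d)
                - (self.sum_d + self.n_d * alpha) * np.log1p(mu_d / alpha)
            )
        )


def _mu_days(state: dict, days: np.ndarray, w: int) -> np.ndarray:
    s1 = expit(state["B1"] * (days - state["M1"]))
    mu = 1.0 + (state["K1"] - 1.0) * s1
    if w:
        s2 = expit(state["B2"] * (days - state["M1"] - state["m"]))
        mu = mu + state["k"] * s2
    return mu


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _default_scales() -> dict[str, float]:
    scales = {name: (hi - lo) / 10.0 for name, (lo, hi) in PRIOR_BOUNDS.items()}
    scales["alpha"] = 10.0  # on the log scale
    return scales


_ADAPT_WINDOW = 25


def _run_chain(series: _Series, cfg: MCMCConfig, rng: np.random.Generator,
               likelihood_weight: float, fixed: Mapping[str, float]):
    init = sample_prior(rng)
    state = {name: getattr(init, name) for name in PARAM_NAMES}
    # clip extreme prior draws of alpha for a numerically sane first evaluation
    state["alpha"] = float(np.clip(state["alpha"], 1e-3, 1e6))
    state.update(fixed)
    state["w"] = int(state["w"])

    scales = _default_scales()
    if cfg.proposal_scales:
        scales.update(cfg.proposal_scales)
    update_names = [n for n in _CONTINUOUS if n not in fixed]
    update_w = "w" not in fixed

    use_lik = likelihood_weight != 0.0

    def _aconst(alpha: float) -> float:
        return series.alpha_const(alpha) if use_lik else 0.0

    def _curve(mu: np.ndarray, alpha: float) -> float:
        return series.curve_part(mu, alpha) if use_lik else 0.0

    days = series.udays
    a_const = _aconst(state["alpha"])
    mu_cur = _mu_days(state, days, state["w"])
    ll_cur = a_const + _curve(mu_cur, state["alpha"])

    n_kept = cfg.draws_per_chain
    kept = {name: np.empty(n_kept, dtype=float) for name in PARAM_NAMES}
    kept_i = 0

    acc_win = {name: 0 for name in update_names}
    try_win = {name: 0 for name in update_names}
    acc_tot = {name: 0 for name in update_names}
    try_tot = {name: 0 for name in update_names}

    pre = cfg.n_adapt + cfg.n_burnin
    total = pre + cfg.n_samples
    weight = likelihood_weight

    for it in range(total):
        adapting = it < pre
        sampling = it >= pre

        for name in update_names:
            if name in _SECOND_PHASE and state["w"] == 0:
                continue  # refreshed from the prior below
            if name == "alpha":
                theta = math.log(state["alpha"])
                theta_new = theta + scales["alpha"] * rng.normal()
                if abs(theta_new) > 700.0:  # exp would over/underflow
                    accept = False
                else:
                    alpha_new = math.exp(theta_new)
                    a_new = _aconst(alpha_new)
                    ll_new = a_new + _curve(mu_cur, alpha_new)
                    log_ratio = weight * (ll_new - ll_cur) - (
                        theta_new**2 - theta**2
                    ) / (2.0 * ALPHA_LOG_SD**2)
                    accept = math.log(rng.random()) < log_ratio
                if accept:
                    state["alpha"] = alpha_new
                    a_const = a_new
                    ll_cur = ll_new
            else:
                lo, hi = PRIOR_BOUNDS[name]
                old = state[name]
                new = old + scales[name] * rng.normal()
                if not (lo <= new <= hi):
                    accept = False
                else:
                    state[name] = new
                    mu_new = _mu_days(state, days, state["w"])
                    ll_new = a_const + _curve(mu_new, state["alpha"])
                    accept = math.log(rng.random()) < weight * (ll_new - ll_cur)
                    if accept:
                        mu_cur = mu_new
                        ll_cur = ll_new
                    else:
                        state[name] = old
            try_win[name] += 1
            acc_win[name] += accept
            if sampling:
                try_tot[name] += 1
                acc_tot[name] += accept
            if adapting and try_win[name] >= _ADAPT_WINDOW:
                rate = acc_win[name] / try_win[name]
                if rate < 0.2:
                    scales[name] = max(scales[name] * 0.7, 1e-9)
                elif rate > 0.45:
                    scales[name] = min(scales[name] * 1.4, 1e7)
                acc_win[name] = try_win[name] = 0

        # pseudo-prior refresh: second-phase parameters carry no likelihood
        # information while w = 0
        if state["w"] == 0:
            for name in _SECOND_PHASE:
                if name not in fixed:
                    lo, hi = PRIOR_BOUNDS[name]
                    state[name] = rng.uniform(lo, hi)

        if update_w:
            mu0 = _mu_days(state, days, 0)
            mu1 = _mu_days(state, days, 1)
            ll0 = a_const + _curve(mu0, state["alpha"])
            ll1 = a_const + _curve(mu1, state["alpha"])
            # full conditional: prior odds 1, so log-odds = weighted ll gap
            z = weight * (ll0 - ll1)
            p1 = 1.0 / (1.0 + math.exp(z)) if z < 700 else 0.0
            w_new = int(rng.random() < p1)
            state["w"] = w_new
            mu_cur, ll_cur = (mu1, ll1) if w_new else (mu0, ll0)

        if sampling and (it - pre + 1) % cfg.thin == 0:
            for name in PARAM_NAMES:
                kept[name][kept_i] = state[name]
            kept_i += 1

    rates = {
        name: (acc_tot[name] / try_tot[name]) if try_tot[name] else math.nan
        for name in update_names
    }
    return kept, rates


def run_mcmc(
    data,
    config: MCMCConfig,
    *,
    likelihood_weight: float = 1.0,
    fixed: Optional[Mapping[str, float]] = None,
) -> PosteriorSamples:
    """Sample the posterior for one count series.

    Parameters
    ----------
    data
        An :class:`~symgrowth.io.ObservationSet` (or any object exposing
        ``days``, ``densities``, ``strain``, ``treatment`` and ``digest()``).
    config
        Chain layout; see :class:`MCMCConfig`.
    likelihood_weight
        Power applied to the likelihood (1 = posterior, 0 = prior).  The
        zero-weight configuration exists for prior-recovery checks.
    fixed
        Mapping of parameter names to values held fixed (not updated),
        e.g. ``{"w": 1, "K1": 140.0}`` to fit only the free remainder.

    Fully reproducible: chain streams derive from ``config.seed`` alone.
    """
    config.validate()
    fixed = dict(fixed or {})
    for key in fixed:
        if key not in PARAM_NAMES:
            raise ValueError(f"unknown fixed parameter {key!r}")

    days = np.asarray(data.days, dtype=float)
    densities = np.asarray(data.densities)
    if days.size == 0:
        raise ValueError("empty observation series")
    series = _Series(days, densities)

    seed_seq = np.random.SeedSequence(config.seed)
    chain_seqs = seed_seq.spawn(config.n_chains)

    draws = {name: np.empty((config.n_chains, config.draws_per_chain)) for name in PARAM_NAMES}
    rate_acc: dict[str, list[float]] = {}
    for c, sub in enumerate(chain_seqs):
        rng = np.random.default_rng(sub)
        kept, rates = _run_chain(series, config, rng, likelihood_weight, fixed)
        for name in PARAM_NAMES:
            draws[name][c] = kept[name]
        for name, r in rates.items():
            rate_acc.setdefault(name, []).append(r)

    return PosteriorSamples(
        draws=draws,
        config=config,
        data_digest=getattr(data, "digest", lambda: "")(),
        strain=getattr(data, "strain", ""),
        treatment=getattr(data, "treatment", ""),
        acceptance_rates={k: float(np.mean(v)) for k, v in rate_acc.items()},
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def psrf(chains: Sequence[Sequence[float]]) -> float:
    """Gelman-Rubin potential scale reduction factor for one scalar parameter.

    Point estimate sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B = n * var(chain means); no degrees-of-freedom correction,
    so cross-checks against corrected implementations may differ by ~0.01.

    Degenerate cases: fewer than 2 chains or fewer than 2 draws per chain is
    an error; zero within-chain variance returns NaN (logged), except when
    every draw in every chain is one identical constant, where the chains
    agree exactly and 1.0 is returned.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a rectangular list of equal-length sequences")
    n_chains, n = arr.shape
    if n_chains < 2:
        raise ValueError("psrf requires at least 2 chains")
    if n < 2:
        raise ValueError("psrf requires at least 2 draws per chain")
    W = float(np.mean(np.var(arr, axis=1, ddof=1)))
    means = arr.mean(axis=1)
    B = n * float(np.var(means, ddof=1))
    if W == 0.0:
        if B == 0.0:
            return 1.0
        logger.warning(
            "zero within-chain variance with disagreeing chain means; PSRF undefined"
        )
        return math.nan
    return math.sqrt(((n - 1) / n * W + B / n) / W)


def psrf_report(samples: PosteriorSamples) -> dict[str, float]:
    """PSRF per model parameter, computed on the retained per-chain draws."""
    report = {}
    for name in PARAM_NAMES:
        report[name] = psrf(samples.draws[name])
        if report[name] > PSRF_BOUND or math.isnan(report[name]):
            logger.warning(
                "PSRF for %s is %.4f (> %.2f): chains may not have converged",
                name, report[name], PSRF_BOUND,
            )
    return report
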