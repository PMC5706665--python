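import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import symgrowth as sg

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def random_valid_params(rng: np.random.Generator, **fixed) -> sg.GrowthParams:
    """A random parameter vector inside the prior supports."""
    vals = {name: rng.uniform(lo, hi) for name, (lo, hi) in sg.PRIOR_BOUNDS.items()}
    vals["w"] = int(rng.random() < 0.5)
    vals["alpha"] = float(np.exp(rng.normal(0.0, 1.5)) * 10)
    vals.update(fixed)
    return sg.GrowthParams(**vals)


def make_samples(n_chains=2, n_kept=100, rng=None, **columns) -> sg.PosteriorSamples:
    """Build a PosteriorSamples object from explicit per-parameter draws.

    Unspecified parameters are filled with valid constants; given columns may
    be pooled 1-d (reshaped) or (n_chains, n_kept) arrays.
    """
    rng = rng or np.random.default_rng(0)
    defaults = {
        "K1": 100.0, "k": 50.0, "B1": 0.5, "B2": 0.2,
        "M1": 10.0, "m": 15.0, "w": 1.0, "alpha": 100.0,
    }
    if columns:
        first = np.asarray(next(iter(columns.values())), dtype=float)
        size = first.size
        assert size % n_chains == 0
        n_kept = size // n_chains
    draws = {}
    for name in sg.PARAM_NAMES:
        if name in columns:
            draws[name] = np.asarray(columns[name], dtype=float).reshape(n_chains, n_kept)
        else:
            draws[name] = np.full((n_chains, n_kept), defaults[name])
    cfg = sg.MCMCConfig(n_chains=n_chains, n_samples=n_kept, thin=1, n_adapt=1, n_burnin=1)
    return sg.PosteriorSamples(draws=draws, config=cfg, strain="a", treatment="b")


@pytest.fixture(scope="session")
def biphasic_fit() -> sg.PosteriorSamples:
    """A real (small) MCMC fit to strongly biphasic synthetic data, shared
    across tests that only need plausible fitted draws."""
    obs = sg.simulate_counts(sg.paper_scenarios()[1], sg.default_design(), seed=42)
    cfg = sg.MCMCConfig(n_chains=2, n_adapt=500, n_burnin=3000, n_samples=3000, thin=6, seed=7)
    return sg.run_mcmc(obs, cfg)
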