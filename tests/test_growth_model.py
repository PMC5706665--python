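"""Unit and property tests for the mean curve, likelihoods and priors."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import symgrowth as sg
from symgrowth.growth_model import ALPHA_LOG_SD, Observation

from conftest import random_valid_params


def params(**kw) -> sg.GrowthParams:
    base = dict(K1=101, k=50, B1=0.5, B2=0.2, M1=10, m=5, w=0, alpha=1.0)
    base.update(kw)
    return sg.GrowthParams(**base)


# K1 > 1: at the degenerate prior edge K1 = 1 the monophasic curve is the
# constant 1 and strictness claims vacuously fail
param_strategy = st.builds(
    sg.GrowthParams,
    K1=st.floats(1.001, 800),
    k=st.floats(1, 500),
    B1=st.floats(0.1, 1),
    B2=st.floats(0.1, 1),
    M1=st.floats(2, 40),
    m=st.floats(2, 40),
    w=st.sampled_from([0, 1]),
    alpha=st.floats(0.01, 1e4),
)


class TestExpectedDensity:
    def test_logistic_midpoint(self):
        # at the inflection day the first phase sits halfway up: 1 + (K1-1)/2
        assert sg.expected_density(params(), 10) == pytest.approx(51.0, abs=1e-12)

    def test_asymptote_is_sum_of_phases(self):
        p = params(w=1)
        assert sg.expected_density(p, 1e6) == pytest.approx(151.0, abs=1e-6)

    def test_direct_formula_evaluation(self):
        # biphasic medians from a real fit, evaluated at the first inflection
        p = sg.GrowthParams(K1=119.1, k=226.27, B1=0.35, B2=0.27,
                            M1=9.15, m=20.27, w=1, alpha=1.0)
        expected = 1 + (119.1 - 1) / 2 + 226.27 / (1 + math.exp(0.27 * 20.27))
        assert sg.expected_density(p, 9.15) == pytest.approx(expected, rel=1e-12)

    def test_rejects_non_finite_day(self):
        with pytest.raises(ValueError, match="day"):
            sg.expected_density(params(), float("nan"))

    def test_rejects_invalid_params_naming_field(self):
        with pytest.raises(ValueError, match="K1"):
            sg.expected_density(params(K1=900), 10)

    @given(p=param_strategy,
           day1=st.floats(0, 25), gap=st.floats(0.5, 5))
    def test_strictly_increasing(self, p, day1, gap):
        """Monotonicity in the pre-saturation window; deep into saturation
        the increments fall below float64 resolution, so strictness is only
        checkable where the curve is still visibly growing."""
        assert sg.expected_density(p, day1 + gap) > sg.expected_density(p, day1)

    @given(p=param_strategy, day=st.floats(0, 200))
    def test_above_unit_floor(self, p, day):
        assert sg.expected_density(p, day) >= 1.0
        # strictly above the floor wherever the logistic terms are resolvable
        assert sg.expected_density(p, p.M1) > 1.0

    @given(p=param_strategy)
    def test_asymptote_reached(self, p):
        day = p.M1 + p.m + 50 / min(p.B1, p.B2)
        assert abs(sg.expected_density(p, day) - (p.K1 + p.w * p.k)) < 1e-6


class TestGrowthRate:
    def test_monophasic_peak_rate(self):
        assert sg.growth_rate(params(), 10) == pytest.approx(12.5, abs=1e-12)

    def test_monophasic_symmetry_about_inflection(self):
        p = params()
        assert sg.growth_rate(p, 13) == pytest.approx(sg.growth_rate(p, 7), rel=1e-12)

    def test_finite_difference_between_phases(self):
        p = params(w=1, m=8)
        h = 1e-5
        fd = (sg.expected_density(p, 18 + h) - sg.expected_density(p, 18 - h)) / (2 * h)
        assert sg.growth_rate(p, 18) == pytest.approx(fd, rel=1e-6)

    def test_finite_difference_over_random_draws(self):
        # h = 1e-4 balances truncation against cancellation when the rate is
        # orders of magnitude below the density
        rng = np.random.default_rng(123)
        h = 1e-4
        for _ in range(100):
            p = random_valid_params(rng)
            # inflection days of the active phases (for a monophasic draw the
            # curve is flat to float precision at M1 + m)
            days = (p.M1, p.M1 + p.m) if p.w == 1 else (p.M1,)
            for day in days:
                fd = (sg.expected_density(p, day + h)
                      - sg.expected_density(p, day - h)) / (2 * h)
                assert sg.growth_rate(p, day) == pytest.approx(fd, rel=1e-6)

    @given(p=param_strategy, day=st.floats(0, 35))
    def test_strictly_positive(self, p, day):
        # beyond ~day 40 at B = 1 the logistic saturates to exactly 1.0 in
        # float64 and the derivative underflows to zero
        assert sg.growth_rate(p, day) > 0


class TestDerivedQuantities:
    def test_biphasic_kmax_is_sum(self):
        dq = sg.derived_quantities(params(K1=100, k=50, w=1))
        assert dq.K_max == 150 and dq.K2 == 150

    def test_monophasic_kmax_is_k1(self):
        dq = sg.derived_quantities(params(K1=100, k=50, w=0))
        assert dq.K_max == 100

    def test_rmax_against_grid_argmax(self):
        # well-separated phases: the rule matches the dense-grid optimum
        p = params(k=41, B1=0.5, B2=0.2, M1=10, m=20, w=1)
        dq = sg.derived_quantities(p)
        grid = np.arange(0.0, 80.0, 1e-3)
        rate = sg.growth_rate(p, grid)
        assert dq.R_M1 == pytest.approx(sg.growth_rate(p, p.M1), rel=1e-12)
        assert dq.R_M2 == pytest.approx(sg.growth_rate(p, p.M1 + p.m), rel=1e-12)
        assert dq.R_max == max(dq.R_M1, dq.R_M2)
        assert dq.R_max == pytest.approx(rate.max(), rel=1e-4)
        assert dq.R_max <= rate.max() * (1 + 1e-12)

    def test_m_rmax_rule(self):
        assert sg.derived_quantities(params(w=0)).M_Rmax == 10
        assert sg.derived_quantities(params(w=1, B1=0.5, B2=0.2)).M_Rmax == 10
        assert sg.derived_quantities(params(w=1, B1=0.2, B2=0.5, m=8)).M_Rmax == 18
        # exact tie resolves to the first phase
        assert sg.derived_quantities(params(w=1, B1=0.3, B2=0.3)).M_Rmax == 10

    @given(p=param_strategy)
    def test_invariant_relations(self, p):
        dq = sg.derived_quantities(p)
        assert dq.K2 == p.K1 + p.k
        assert dq.M2 == p.M1 + p.m
        assert dq.K_max == (p.K1 if p.w == 0 else dq.K2)
        assert dq.R_max >= max(dq.R_M1, dq.R_M2) - 1e-12 if p.w == 1 else dq.R_max >= 0


class TestConditionalLikelihood:
    def test_zero_count_unit_rate(self):
        p = params(K1=1 + 1e-9)  # mu ~= 1 at late day
        ll = sg.log_likelihood_conditional(p, 1.0, Observation(day=1000.0, density=0))
        assert ll == pytest.approx(-1.0, abs=1e-8)

    def test_matches_scipy_poisson(self):
        # mu * rho = 5 at the inflection: 1 + (9-1)/2 = 5
        p = params(K1=9, w=0)
        ll = sg.log_likelihood_conditional(p, 1.0, Observation(day=10.0, density=5))
        assert ll == pytest.approx(stats.poisson.logpmf(5, 5.0), rel=1e-12)
        assert ll == pytest.approx(math.log(5**5 * math.exp(-5) / math.factorial(5)), rel=1e-10)

    def test_normalization(self):
        p = params(K1=5, w=0)  # mu = 3 at day M1
        total = sum(
            math.exp(sg.log_likelihood_conditional(p, 1.0, Observation(day=10.0, density=d)))
            for d in range(201)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            sg.log_likelihood_conditional(params(), 0.0, Observation(day=1.0, density=1))
        with pytest.raises(ValueError):
            sg.log_likelihood_conditional(params(), 1.0, Observation(day=1.0, density=-1))


class TestMarginalLikelihood:
    def test_geometric_special_case(self):
        # mu = 1, alpha = 1 -> NB reduces to Geometric(1/2)
        p = params(K1=1 + 1e-12, alpha=1.0)
        ll = sg.log_likelihood_marginal(p, Observation(day=1000.0, density=0))
        assert ll == pytest.approx(math.log(0.5), abs=1e-9)

    def test_poisson_limit(self):
        p = params(K1=9, w=0, alpha=1e6)
        marg = sg.log_likelihood_marginal(p, Observation(day=10.0, density=5))
        cond = sg.log_likelihood_conditional(p, 1.0, Observation(day=10.0, density=5))
        assert marg == pytest.approx(cond, abs=1e-3)

    def test_matches_scipy_nbinom(self):
        p = params(K1=19, w=0, alpha=2.0)  # mu = 10 at day M1
        for d in (0, 3, 10, 40):
            ll = sg.log_likelihood_marginal(p, Observation(day=10.0, density=d))
            ref = stats.nbinom.logpmf(d, 2.0, 2.0 / (2.0 + 10.0))
            assert ll == pytest.approx(ref, rel=1e-10)

    def test_moments_by_pmf_summation(self):
        p = params(K1=19, w=0, alpha=2.0)  # mu = 10
        d = np.arange(501)
        logp = np.array([
            sg.log_likelihood_marginal(p, Observation(day=10.0, density=int(x))) for x in d
        ])
        pmf = np.exp(logp)
        mean = float(np.sum(d * pmf))
        var = float(np.sum(d**2 * pmf) - mean**2)
        assert mean == pytest.approx(10.0, rel=1e-6)
        assert var == pytest.approx(10.0 + 100.0 / 2.0, rel=1e-6)

    def test_moments_over_random_mu_alpha(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            mu = rng.uniform(2, 30)
            alpha = rng.uniform(0.5, 50)
            p = params(K1=2 * mu - 1, w=0, alpha=alpha)  # mu at inflection
            d = np.arange(int(mu + 30 * math.sqrt(mu + mu**2 / alpha)))
            pmf = np.exp([
                sg.log_likelihood_marginal(p, Observation(day=10.0, density=int(x)))
                for x in d
            ])
            mean = float(np.sum(d * pmf))
            var = float(np.sum(d**2 * pmf) - mean**2)
            assert mean == pytest.approx(mu, rel=1e-4)
            assert var == pytest.approx(mu + mu**2 / alpha, rel=1e-4)

    def test_mixture_equivalence_monte_carlo(self):
        """Averaging the conditional Poisson likelihood over rho ~ Gamma(a, a)
        reproduces the negative-binomial marginal within MC error."""
        rng = np.random.default_rng(2024)
        p = params(K1=41, w=0, alpha=3.0)  # mu = 21 at day M1
        obs = Observation(day=10.0, density=25)
        rho = rng.gamma(3.0, 1.0 / 3.0, size=100_000)
        lik = np.exp([sg.log_likelihood_conditional(p, r, obs) for r in rho])
        mc_mean = lik.mean()
        mc_se = lik.std(ddof=1) / math.sqrt(lik.size)
        assert abs(mc_mean - math.exp(sg.log_likelihood_marginal(p, obs))) < 3 * mc_se


class TestLogPrior:
    def test_outside_support_is_neg_inf(self):
        assert sg.log_prior(params(K1=900)) == -math.inf

    def test_switching_prior_is_symmetric(self):
        assert sg.log_prior(params(w=1)) == sg.log_prior(params(w=0))
        assert math.isfinite(sg.log_prior(params(w=1)))

    def test_closed_form_value(self):
        p = params(K1=400.5, k=250.5, B1=0.55, B2=0.55, M1=21, m=21, w=1, alpha=1.0)
        expected = (
            -math.log(799) - math.log(499) - 2 * math.log(0.9) - 2 * math.log(38)
            + math.log(0.5)
            + stats.lognorm(s=ALPHA_LOG_SD, scale=1.0).logpdf(1.0)
        )
        assert sg.log_prior(p) == pytest.approx(expected, rel=1e-12)


def test_prior_bound_override_context():
    with sg.override_prior_bounds(K1=(1, 400)):
        assert sg.PRIOR_BOUNDS["K1"] == (1, 400)
        assert sg.log_prior(params(K1=500)) == -math.inf
    assert sg.PRIOR_BOUNDS["K1"] == (1, 800)
    assert math.isfinite(sg.log_prior(params(K1=500)))
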