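# symgrowth

Bayesian biphasic logistic growth analysis for microalgal cell-count time
series.

## The problem

Batch cultures of microalgae (e.g. *Symbiodinium* dinoflagellates) are
counted repeatedly over a ~9-week growth period. Some strain × treatment
series grow as one logistic wave to a plateau; others are **biphasic**: an
initial logistic rise to an intermediate plateau, then a second rise to a
higher final density. Replicate hemocytometer counts are noisy integer data
with variance well above the Poisson mean. The questions of interest are the
asymptotic densities, timing, and steepness of each growth phase, whether a
series is biphasic at all, and whether these quantities differ between
series.

## The model

With time `n` in days and density in units of 10⁴ cells ml⁻¹, the mean curve
is a sum of up to two logistic terms,

    mu(n) = 1 + (K1 − 1)·logistic(B1(n − M1)) + w·k·logistic(B2(n − M1 − m))

where `w ∈ {0, 1}` switches the second phase on, and counts are negative
binomial around the curve: `D ~ Poisson(mu·rho)` with `rho ~ Gamma(alpha,
alpha)`, giving variance `mu + mu²/alpha`. All eight parameters — `K1, k,
B1, B2, M1, m, w, alpha` — are sampled by a Metropolis-within-Gibbs MCMC
with an exact Gibbs update for `w`, so `Pr(biphasic)` is the posterior mean
of `w` and every derived quantity (`K_max`, `M2`, `R_max`, …) is averaged
over both model forms per draw. See [docs/methods.md](docs/methods.md) for
the full specification, priors, and numerical details.

## Worked example

Simulate two synthetic series (one strongly biphasic truth with final
plateau K1 + k = 472.76, one monophasic with K1 = 150), fit both with the
desk-scale sampler (4 chains × 20,000 sampling draws after 20,000 burn-in),
and compare them:

```bash
symgrowth simulate --out-dir demo --seed 11 \
    --scenario biphasic_strong --scenario monophasic_low
symgrowth fit demo/counts_*.csv --out-dir demo/fits --seed 11
symgrowth compare demo/fits/draws_*.csv --out-dir demo/fits
symgrowth plot demo/counts_*.csv --fit-dir demo/fits --out-dir demo/figs
```

`demo/fits/summary.csv` then contains (selected columns, one row per series;
medians with equal-tailed 95% credible intervals):

| series | Pr(biphasic) | K_max | M1 | B1 | R_max |
|---|---|---|---|---|---|
| biphasic_strong | 1.000 | 483.7 [465.9, 503.5] | 7.95 [7.65, 8.33] | 0.79 [0.60, 0.97] | 28.2 [24.2, 32.2] |
| monophasic_low | 0.012 | 147.2 [143.8, 150.6] | 9.88 [9.62, 10.15] | 0.41 [0.39, 0.44] | 15.1 [14.2, 16.0] |

Both intervals cover their truths (472.76 and 150), the switching indicator
cleanly separates the two regimes, and `demo/fits/psrf.csv` reports maximum
Gelman–Rubin PSRF 1.0083 and 1.0002 — both below the 1.08 convergence bound.
`demo/fits/comparisons.csv` flags the between-series differences: the
proportion of paired posterior draws with `K_max(A) − K_max(B) > 0` is
1.0000 (significant, `*`), and for `M1` it is 0.0000 (the biphasic series
inflects earlier — also significant).

The same pipeline is available as a library:

```python
import symgrowth as sg

obs = sg.simulate_counts(sg.paper_scenarios()[1], sg.default_design(), seed=11)
samples = sg.run_mcmc(obs, sg.MCMCConfig(seed=11))
print(sg.summarize(samples).table)      # medians + 95% CIs for all quantities
print(sg.psrf_report(samples))          # per-parameter PSRF
```

## Repository layout

- `src/symgrowth/growth_model.py` — curve, priors, likelihoods, derived quantities
- `src/symgrowth/inference.py` — MCMC sampler, PSRF diagnostics
- `src/symgrowth/synthetic_data.py` — experiment design and count generator
- `src/symgrowth/posterior_analysis.py` — per-draw derivation, summaries, comparisons
- `src/symgrowth/io.py`, `src/symgrowth/cli.py` — count-table/config I/O and the `symgrowth` CLI
- `docs/methods.md` — model, sampler, and numerical conventions
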