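# tacticlearn

Social versus individual learning in football managers' choice of
starting formation.

When a manager decides whether to start the era's dominant formation —
4231 during the 2010s — two information sources compete: their own recent
use of and success with it (individual learning), and its use and success
across every manager in their division (social learning).  `tacticlearn`
turns that question into a reproducible inference pipeline for match-level
league data: moving-window predictor construction, four hierarchical
Bayesian logistic choice models compared by WAIC, the population:personal
reliance ratio, a randomisation null for between-manager strategy
variation, and a manager-level quadratic test of whether the mix of
information sources predicts success.  A built-in synthetic-league
generator makes every stage testable — and parameter recovery measurable —
without any external data.  It is aimed at cultural-evolution and
social-learning researchers working with observational choice data.

## The model

Each team-side of each match is one observation: did manager *m* of
division *d* start the focal formation?  With an X-day moving window
(default 30 days, reset at each season start) supplying personal
predictors (a) use `p_use`, (b) relative win rate `p_win`, interactions
(c) `p_use x p_win`, (d) `p_use x o_win`, and population analogues
(e)–(h), plus home/away index intercepts and season-long team strength:

    y_i ~ Bernoulli(p_i)
    logit p_i = alpha[home_i] + a_m + a_d + sum_t (beta_t + b_t,m + b_t,d) x_t,i

    alpha, beta ~ Normal(0, 1.5)        a_., b_. ~ Normal(0, sigma_group,term)
    sigma ~ Exponential(1)

Varying intercepts by manager and division in every model; varying slopes
for the use and win-rate predictors by manager, and for the use
predictors by division.  The *null*, *personal*, *population* and *full*
models nest by which predictor block they include.  Sampling is a
self-contained No-U-Turn sampler with analytic, numba-compiled gradients;
convergence is reported via split R-hat, ESS and divergence counts.
See `docs/methods.md` for the full account.

## Worked example

Simulate a league system whose managers truly weigh personal and
population information equally (both use coefficients 0.8), then run the
analysis end to end:

```python
import tacticlearn as tl
from tacticlearn.hierarchical_models import McmcSettings, ModelSpec, compare, fit

cfg = tl.SimulationConfig.recovery_default()   # known beta_p_use = beta_g_use = 0.8
sim = tl.simulate(cfg, seed=1)
obs = tl.to_observations(sim.matches)
design = tl.build_design(obs, tl.WindowConfig(x_days=cfg.window_days),
                         season_starts=sim.season_starts)

settings = McmcSettings(chains=2, warmup=500, samples=400)
fits = {n: fit(design, ModelSpec.named(n), settings, seed=i)
        for i, n in enumerate(("null", "personal", "population", "full"))}
print(compare(list(fits.values())).round(2).to_string(index=False))
ratio = tl.use_ratio(fits["full"]).iloc[0]
print(f"population:personal ratio: mean {ratio['mean']:.2f}, "
      f"89% CI [{ratio['lower']:.2f}, {ratio['upper']:.2f}]")
```

Output:

```
     model    waic  p_waic  d_waic  weight    se  d_se
  personal 3135.76   73.10    0.00    0.66 50.79  0.00
      full 3137.09   89.04    1.33    0.34 51.14  6.04
population 3160.07   80.58   24.30    0.00 50.45 15.55
      null 3167.74   63.16   31.98    0.00 49.87 16.13
population:personal ratio: mean 0.93, 89% CI [0.09, 1.95]
```

The comparison firmly rejects the null and population-only models.
Personal and full are statistically tied (dWAIC 1.3 against a dSE of 6):
the full model carries the two real effects plus six truly-zero
coefficients, so its extra penalty (pWAIC 89 vs 73) roughly offsets its
extra fit — the expected behaviour on these generating values.  In the
full model both use coefficients are recovered with intervals excluding
zero (`beta_p_use` 0.66 [0.45, 0.89], `beta_g_use` 0.57 [0.08, 1.06]),
and the ratio posterior centres near the true value 1.

The same stages run from the shell via the `tacticlearn` CLI
(`simulate-league`, `ingest`, `predictors`, `fit`, `compare`, `test`,
`recover`, `run`); `tacticlearn run --config run.yml` executes the whole
pipeline and writes the result tables plus a manifest with config/data
hashes and per-stage diagnostics.

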