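# Methods

`tacticlearn` quantifies how football managers weigh two information
sources when deciding whether to start the dominant *focal* formation
(4231 by default): their own recent experience with it (individual
learning) and its recent use and success across all managers in their
division (social learning).  This note documents the model, the predictor
construction, the estimation machinery, the synthetic-league generator and
the design choices behind each.

## Unit of analysis and predictors

Every match yields two *formation observations*, one per team-side.  The
outcome is binary: did that manager start the focal formation?  For each
observation, predictors summarise the X calendar days before the match
(never the match day itself), restricted to the same division and season:

| term | meaning | range |
|---|---|---|
| `p_use` | manager's focal-use proportion in the window, centred on 0.5 | [-0.5, 0.5] |
| `p_win` | manager's focal win rate minus their non-focal win rate | [-1, 1] |
| `p_use_x_p_win` | product of the two above | |
| `p_use_x_o_win` | `p_use` x manager's overall window win rate, centred on the all-manager window rate | |
| `g_use` | division-wide focal-use proportion, centred on 0.5 | [-0.5, 0.5] |
| `g_win` | division-wide focal minus non-focal win rate | [-1, 1] |
| `g_use_x_g_win`, `g_use_x_o_win` | the population analogues | |
| `team_strength` | team's full-season win proportion centred on the division-season team mean (control) | |
| home/away | index intercepts (control) | |

The window length X defaults to 30 days, with 20/40/60 supported as
sensitivity variants.  Windows reset at each season start; observations in
a season's first X days are excluded as outcomes (they lack a full
window) but still serve as window content for later observations.  The
Bundesliga's long winter pause is compressed to 10 idle days by shifting
post-break dates earlier, so windows always contain prior games; season
boundary dates live in an editable YAML calendar and only decide which
early-season games are excluded.

Two conventions for "win rate" are implemented because draw handling is
genuinely ambiguous in this domain: `"win"` (draw = 0, the literal
proportion of games won, the default) and `"points"` (draw = 0.5, a
point-share reading).  Both are exposed everywhere a win rate enters.

**Undefined window statistics.**  A newly appointed manager has no window
games; a manager with only focal (or only non-focal) window games has no
win-rate difference.  Both are imputed with 0 — the no-information value
on these centred scales — so the observation is retained; companion
`*_imputed` flags and window game counts record how much information was
actually available.  `team_strength` deliberately uses the whole season,
including future games: it proxies season-constant squad ability, not
information available on match day.

Two re-analysis switches reproduce common robustness checks: removing the
chooser's own team's games from the population window (so social
information contains no personal information), and adding opponent
strength and opponent-focal-formation controls.

## The choice models

Four Bayesian multilevel logistic regressions are fitted to the same
design: *null* (controls only), *personal* (+ the four personal terms),
*population* (+ the four population terms) and *full* (all eight).  With
manager m and division d, the linear predictor is

    logit p_i = alpha[home_i] + a_m + a_d + sum_t (beta_t + b_t,m + b_t,d) x_t,i

Home and away get separate intercepts (an index variable, no shared
global intercept).  All models have varying intercepts by manager and
division.  Use and win-rate predictors get varying slopes by manager;
use predictors additionally vary by division (division-level win-rate
slopes are off by default and available as a switch) — the division level
is what lets one league respond to personal information very differently
from the others, which is exactly the pattern of interest.

Priors are weakly informative on the logit scale: Normal(0, 1.5) for
alpha and every beta, Exponential(1) for each group SD.  Varying effects
use an independent (diagonal) non-centred parameterization, z ~ N(0,1)
scaled by its group SD.  We deliberately omit cross-effect correlations
within a group: the acceptance-bearing quantities (coefficients, group
SDs, ratios) are defined without them, and the diagonal form keeps the
hand-written gradient simple and fast.  All prior settings are plain
dataclass fields and can be substituted.

## Estimation

No general-purpose MCMC engine is part of the package's dependency
footprint; sampling is a self-contained No-U-Turn sampler (slice variant)
over the unconstrained parameter vector, with:

- analytic gradients of the full log posterior, compiled with numba
  (~50 us per evaluation at 600 observations);
- dual-averaging step-size adaptation to a 0.9 target acceptance
  statistic;
- one diagonal mass-matrix update estimated from the middle half of
  warmup, Stan-style regularized towards unit scale;
- tree depth capped at 9 doublings; an energy error above 1000 cuts the
  trajectory and is counted as a divergence.

Defaults are 4 chains of 1000 warmup + 1000 draws; the test suite and the
acceptance script use 2 chains of 500 + 400, which our diagnostics show
is sufficient at desk scale (split R-hat <= ~1.03, bulk ESS in the
hundreds for the fixed effects).  Convergence is summarised with arviz
split R-hat and ESS; a fit with any divergence or R-hat > 1.01 is
returned with a warning and a `converged: False` flag rather than
discarded — the caller decides.  Everything is deterministic given the
seed (per-chain generators spawned from one `SeedSequence`).

Model comparison uses WAIC computed from the pointwise log-likelihood
matrix: `lppd_i = log mean_s exp(ll_si)` via log-sum-exp,
`p_i = var_s(ll_si)` with the sample-variance (ddof = 1) convention of
the R ecosystem (arviz uses the population variance; the test suite
pins the exact rescaling between the two), `WAIC = -2(lppd - p)`,
Akaike-style weights from dWAIC, and dSE from the pointwise differences
against the best model.  Comparisons refuse models fitted to different
observation sets.

## Hypothesis procedures

**Model comparison / effect presence.**  WAIC table plus 89% percentile
intervals (5.5%–94.5% posterior quantiles) for every coefficient.

**Population:personal ratio.**  r = beta_g_use / beta_p_use computed *per
posterior draw*, then summarised — a ratio of posterior means cannot
yield an interval and is reported only as a side statistic.  Group scopes
add that group's varying slope offsets to numerator and denominator
before dividing.  Draws with |denominator| < 1e-8 are counted, never
silently dropped, and a 0.5%-per-tail trimmed mean guards the point
summary against the heavy tails a near-zero denominator induces; above
5% near-zero draws the summary carries a warning.

**Randomisation null for strategy variation.**  Formation labels and
(won, drew) outcome pairs are independently permuted across observations
within each division-season (a global permutation is available),
preserving marginal frequencies while severing manager-level
associations; predictors are rebuilt and the same model refitted.  The
posterior of each varying-effect SD on real data is contrasted
draw-by-draw with its randomised counterpart; one randomised replicate is
the default, matching common practice, with a multi-replicate mode for
stability.

**Quadratic success model.**  One row per manager: relative win rate
(per-game success centred on the division-season mean, averaged over the
manager's games) regressed on the manager-scope ratio and its square,
win_rate ~ Normal(a + b1 r + b2 r^2, sigma).  The posterior is exact
conjugate normal-inverse-gamma sampling — coefficients N(0, sigma^2 1e4),
sigma^2 ~ InvGamma(2, 0.002) in win-rate units — weak enough that
estimates track least squares (the tests pin this against an OLS
oracle).  An adaptive trade-off between information sources would show
as b2's 89% interval entirely below zero.

**Prediction curves and joint posteriors.**  Curves evaluate the
average-manager/average-division posterior predictive across the use
range with the matching win-rate predictor held at a chosen offset
(interactions included, everything else at 0).  Per-manager joint
posteriors of (personal reliance, social reliance) are the fixed slopes
plus that manager's offsets, with an 80% covariance ellipse.

## The synthetic league

The generator exists so the whole pipeline is testable without any
external data, and so recovery of known parameters is measurable.  Per
division-season it plays a circle-method double round-robin (each pair
meets home and away, no team twice per day) spread evenly over the
season; defaults are 2 divisions x 10 teams x 2 seasons of 180 days
(~360 matches), a deliberate desk scale.  A paper-scale preset
(5 x 20 x 5) exists for slow full-size runs.

Choices follow the full model exactly: on every match day the generator
computes the same window statistics the analysis later reconstructs
(shared scalar code path, same imputation), evaluates the true-parameter
choice probability through the same `likelihood()` the models use, and
draws the choice.  A calibration test bins realised choices by this
probability and checks the diagonal.  Outcomes come from a logistic
contest on latent team strengths plus home advantage, with a fixed draw
probability carved out symmetrically — the simplest outcome model that
makes win-rate predictors informative.  By default formation choice has
no causal effect on winning, so the quadratic model's null is true and
testable; a `formation_win_effect` switch enables trade-off experiments.
Non-focal choices get cosmetic labels (433/442/352/343) so descriptive
summaries look league-like.

During each season's first X days managers choose from the
intercept-only probability, plus a per-division-season offset drawn with
sd `burn_in_logit_sd` (default 1.0).  This burn-in spread emulates the
very different levels at which real division-seasons enter an observation
window — real divisions in the same year have carried focal shares from
under 0.10 to 0.78 — and, because the offset vanishes after burn-in, all
modelled observations still follow the choice model exactly; the spread
only diversifies initial conditions.  Default group SDs (division
intercept 1.0, manager intercept 0.5, slopes 0.2–0.3) mirror the same
observation: between-division differences in focal use are order-one on
the logit scale.

What the generator does **not** emulate: goal counts and scorelines,
squad composition and transfers, managerial turnover (off by default;
a turnover rate switch exists), opponent anticipation, and any effect of
formation on winning.  Passing tests therefore show that the inference
machinery recovers the model's own data-generating process at realistic
noise levels — not that the substantive conclusions about real leagues
are correct.

## The recovery design

Parameter-recovery experiments use a dedicated configuration:
**10 divisions x 8 teams x 3 seasons, X = 20, burn-in spread 2.0**, with
both use coefficients at 0.8.  The reason is an information-structure
fact uncovered while designing the experiment: the population-use
predictor varies at the division-day level and its latent level varies
per division-season, so information about `beta_g_use` accrues with
division-seasons, not with observations.  A league-shaped 2 x 10 x 2
dataset contains ~4 division-seasons and cannot pin the population
coefficient (its posterior sd exceeds 0.6 there); trading team count for
division count at fixed compute (30 division-seasons, ~2900 eligible
observations) gives both use coefficients comparable identification.
The shorter 20-day window (a standard sensitivity variant) adds
exogenous day-level variation in the population share, and the wider
burn-in spread widens the spread of initial conditions.  At this design,
across 20 replicates the posterior means of both use coefficients carry
|bias| < 0.1 and their 89% intervals exclude zero in ~9 of 10 replicates.

## Problem sizes and numerical conventions

- Test suite and acceptance script: 2 chains x (500 warmup + 400 draws);
  recovery 20 replicates at the recovery design; randomisation harness
  5 replicates per condition at the 2 x 10 x 2 scale with weekly rounds
  (126-day seasons, so personal windows hold ~4 games as in real
  leagues).  The harness's heterogeneous condition sets the manager
  use-slope SDs to 1.2; its null condition is fully exchangeable
  (no use effects, no slope heterogeneity), since real fixed effects
  alone already separate real from randomised SD posteriors.
- Proportions are ratios of small integer counts and centred afterwards;
  the brute-force oracle reproduces the design matrix bit-for-bit.
- 89% percentile intervals throughout (5.5%/94.5% quantiles); interval
  "presence" means the interval excludes 0 (or 1, for the ratio).
- Ratio trimming: 0.5% per tail; near-zero denominator threshold 1e-8.
- Same-day games are simultaneous: never part of each other's windows.

## Known limitations

- The population-use coefficient is intrinsically weakly identified in
  small league systems; in few-division configurations its posterior is
  wide and partially exchangeable with the personal-use coefficient
  (their windows overlap — a manager's games are part of their
  division's games) and with division varying intercepts.  The recovery
  design above is shaped around this, and single-league analyses should
  not expect a sharp population effect.
- Manager varying intercepts absorb persistent personal style; because
  `p_use` is a lagged function of the manager's own choices, unmodelled
  intercept heterogeneity inflates naive (non-hierarchical) estimates of
  the personal-use effect — one reason the multilevel structure is not
  optional here.
- The diagonal varying-effects structure ignores intercept-slope
  correlations; group SDs and coefficients remain interpretable, but
  correlation-based summaries are out of scope.
- WAIC is the only comparison criterion implemented; recency-weighted
  windows and memory-decay learning models are out of scope.
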