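"""Bayesian multilevel logistic models of the focal-formation choice.

Four nested model specifications are fitted to the design matrix built by
:mod:`tacticlearn.window_predictors`:

null        home/away intercepts + team strength, varying intercepts only
personal    + the four personal predictors, varying slopes for personal
            use and win rate
population  + the four population predictors, varying slopes for population
            use and win rate
full        all eight predictors and both sets of varying slopes

Every model has varying intercepts by manager and by division.  Use-slopes
vary by manager and by division; win-rate slopes vary by manager only
unless ``division_winrate_slopes`` is set.  The linear predictor for
observation i with manager m and division d is

    logit p_i = alpha[home_i] + a_m + a_d
                + sum_t (beta_t + b_{t,m} + b_{t,d}) x_{t,i}

with b terms present only where the spec declares a varying slope.  Priors
are weakly informative on the logit scale — Normal(0, 1.5) for alpha and
beta, Exponential(1) for every group standard deviation — with independent
(diagonal) non-centred varying effects.  Sampling is adaptive HMC with
analytic gradients (:mod:`tacticlearn._hmc`); convergence is summarised
with split-chain R-hat and effective sample sizes via arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit

from ._hmc import sample_chain
from .window_predictors import CONTROL_TERMS, OPPONENT_TERMS

MODEL_NAMES = ("null", "personal", "population", "full")
PERSONAL_TERMS = ("p_use", "p_win", "p_use_x_p_win", "p_use_x_o_win")
POPULATION_TERMS = ("g_use", "g_win", "g_use_x_g_win", "g_use_x_o_win")

INTERVAL_PROB = 0.89          # central posterior interval, 5.5%..94.5%
RHAT_THRESHOLD = 1.01


class SpecificationError(ValueError):
    """A parameter required by the model specification is missing."""


@dataclass(frozen=True)
class Priors:
    fixed_sd: float = 1.5          # Normal sd for alpha and beta (logit scale)
    group_sd_rate: float = 1.0     # Exponential rate for group SDs


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the linear predictor and which of them vary by group."""

    name: str
    fixed_terms: tuple[str, ...]
    manager_slopes: tuple[str, ...]
    division_slopes: tuple[str, ...]
    priors: Priors = field(default_factory=Priors)

    @classmethod
    def named(cls, name: str, opponent_controls: bool = False,
              division_winrate_slopes: bool = False,
              priors: Priors | None = None) -> "ModelSpec":
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
        controls = tuple(CONTROL_TERMS) + (
            tuple(OPPONENT_TERMS) if opponent_controls else ())
        personal = name in ("personal", "full")
        population = name in ("population", "full")
        fixed = controls
        mgr: tuple[str, ...] = ()
        div: tuple[str, ...] = ()
        if personal:
            fixed += PERSONAL_TERMS
            mgr += ("p_use", "p_win")
            div += ("p_use",) + (("p_win",) if division_winrate_slopes else ())
        if population:
            fixed += POPULATION_TERMS
            mgr += ("g_use", "g_win")
            div += ("g_use",) + (("g_win",) if division_winrate_slopes else ())
        return cls(name=name, fixed_terms=fixed, manager_slopes=mgr,
                   division_slopes=div, priors=priors or Priors())

    @property
    def manager_effects(self) -> tuple[str, ...]:
        return ("intercept",) + self.manager_slopes

    @property
    def division_effects(self) -> tuple[str, ...]:
        return ("intercept",) + self.division_slopes


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    target_accept: float = 0.9
    max_depth: int = 9          # NUTS tree-doubling limit


@dataclass
class PosteriorDraws:
    """Posterior samples, pointwise log-likelihoods and diagnostics."""

    spec: ModelSpec
    draws: dict[str, np.ndarray]          # name -> (chains, samples[, levels])
    loglik: np.ndarray                    # (chains*samples, n_obs)
    diagnostics: dict
    manager_levels: list[str]
    division_levels: list[str]
    obs_ids: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return self.loglik.shape[0]

    @property
    def n_obs(self) -> int:
        return self.loglik.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains flattened: (S,) or (S, levels)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])


# ---------------------------------------------------------------------------
# pointwise likelihood (also drives the synthetic-league generator)
# ---------------------------------------------------------------------------

def likelihood(params: dict, row: dict, spec: ModelSpec) -> float:
    """Probability of the focal choice for one observation.

    ``params`` holds ``alpha_home``/``alpha_away``, a ``beta`` mapping over
    ``spec.fixed_terms``, and ``manager_effects`` / ``division_effects``
    mappings over the spec's varying effects (offsets for this row's
    groups).  ``row`` maps term names to predictor values plus ``is_home``.
    """
    try:
        eta = params["alpha_home"] if row.get("is_home", True) else params["alpha_away"]
        eta += params["manager_effects"]["intercept"]
        eta += params["division_effects"]["intercept"]
        for t in spec.fixed_terms:
            coef = params["beta"][t]
            if t in spec.manager_slopes:
                coef += params["manager_effects"][t]
            if t in spec.division_slopes:
                coef += params["division_effects"][t]
            eta += coef * row[t]
    except KeyError as err:
        raise SpecificationError(f"missing parameter or predictor {err}") from err
    return float(expit(eta))


# ---------------------------------------------------------------------------
# posterior
# ---------------------------------------------------------------------------

@njit(cache=True)
def _logp_grad_kernel(theta, y, home, X, m_idx, d_idx, m_cov, d_cov,
                      M, D, s2, rate):
    """Log posterior and gradient in one pass (numba-compiled)."""
    N, F = X.shape
    Km = m_cov.shape[0]
    Kd = d_cov.shape[0]
    base_zm = 2 + F
    base_zd = base_zm + Km * M
    base_tm = base_zd + Kd * D
    base_td = base_tm + Km

    alpha = theta[0:2]
    beta = theta[2:2 + F]
    sig_m = np.exp(theta[base_tm:base_tm + Km])
    sig_d = np.exp(theta[base_td:base_td + Kd])

    logp = 0.0
    grad = np.zeros(theta.size)
    for i in range(N):
        e = alpha[home[i]]
        for f in range(F):
            e += X[i, f] * beta[f]
        for k in range(Km):
            e += sig_m[k] * theta[base_zm + k * M + m_idx[i]] * m_cov[k, i]
        for k in range(Kd):
            e += sig_d[k] * theta[base_zd + k * D + d_idx[i]] * d_cov[k, i]
        if e > 0.0:
            p = 1.0 / (1.0 + np.exp(-e))
            l1pe = e + np.log1p(np.exp(-e))
        else:
            ex = np.exp(e)
            p = ex / (1.0 + ex)
            l1pe = np.log1p(ex)
        logp += y[i] * e - l1pe
        w = y[i] - p
        grad[home[i]] += w
        for f in range(F):
            grad[2 + f] += X[i, f] * w
        for k in range(Km):
            j = base_zm + k * M + m_idx[i]
            grad[j] += sig_m[k] * w * m_cov[k, i]
            grad[base_tm + k] += sig_m[k] * w * m_cov[k, i] * theta[j]
        for k in range(Kd):
            j = base_zd + k * D + d_idx[i]
            grad[j] += sig_d[k] * w * d_cov[k, i]
            grad[base_td + k] += sig_d[k] * w * d_cov[k, i] * theta[j]

    # priors: Normal(0, s) on alpha/beta, Normal(0,1) on z,
    # Exponential(rate) on sigma with the log-transform Jacobian
    for j in range(2 + F):
        logp += -0.5 * theta[j] * theta[j] / s2
        grad[j] += -theta[j] / s2
    for j in range(base_zm, base_tm):
        logp += -0.5 * theta[j] * theta[j]
        grad[j] += -theta[j]
    for k in range(Km):
        logp += theta[base_tm + k] - rate * sig_m[k]
        grad[base_tm + k] += 1.0 - rate * sig_m[k]
    for k in range(Kd):
        logp += theta[base_td + k] - rate * sig_d[k]
        grad[base_td + k] += 1.0 - rate * sig_d[k]
    return logp, grad


class _Posterior:
    """Packed log-posterior with analytic gradient for one model/design."""

    def __init__(self, design: pd.DataFrame, spec: ModelSpec):
        if design.empty:
            raise ValueError("empty design matrix")
        self.spec = spec
        self.y = design["is_focal"].to_numpy(dtype=float)
        self.home = np.where(design["is_home"].to_numpy(dtype=bool), 0, 1)
        self.X = design[list(spec.fixed_terms)].to_numpy(dtype=float)
        self.m_idx, m_levels = pd.factorize(design["manager"], sort=True)
        self.d_idx, d_levels = pd.factorize(design["division"], sort=True)
        self.manager_levels = list(m_levels)
        self.division_levels = list(d_levels)
        self.M, self.D = len(m_levels), len(d_levels)
        self.n = len(design)
        ones = np.ones(self.n)
        self.m_cov = np.ascontiguousarray(
            [ones] + [design[t].to_numpy(dtype=float)
                      for t in spec.manager_slopes])
        self.d_cov = np.ascontiguousarray(
            [ones] + [design[t].to_numpy(dtype=float)
                      for t in spec.division_slopes])
        self.Km, self.Kd = len(self.m_cov), len(self.d_cov)
        self.F = self.X.shape[1]
        self.X = np.ascontiguousarray(self.X)
        self.m_idx = self.m_idx.astype(np.int64)
        self.d_idx = self.d_idx.astype(np.int64)
        self.home = self.home.astype(np.int64)
        # layout: alpha(2) | beta(F) | z_m(Km*M) | z_d(Kd*D) | tau_m(Km) | tau_d(Kd)
        self.dim = 2 + self.F + self.Km * self.M + self.Kd * self.D + self.Km + self.Kd

    def unpack(self, theta):
        o = 0
        alpha = theta[o:o + 2]; o += 2
        beta = theta[o:o + self.F]; o += self.F
        z_m = theta[o:o + self.Km * self.M].reshape(self.Km, self.M); o += self.Km * self.M
        z_d = theta[o:o + self.Kd * self.D].reshape(self.Kd, self.D); o += self.Kd * self.D
        tau_m = theta[o:o + self.Km]; o += self.Km
        tau_d = theta[o:o + self.Kd]
        return alpha, beta, z_m, z_d, tau_m, tau_d

    def eta(self, theta):
        alpha, beta, z_m, z_d, tau_m, tau_d = self.unpack(theta)
        sig_m, sig_d = np.exp(tau_m), np.exp(tau_d)
        eta = alpha[self.home] + self.X @ beta
        for k in range(self.Km):
            eta += sig_m[k] * z_m[k][self.m_idx] * self.m_cov[k]
        for k in range(self.Kd):
            eta += sig_d[k] * z_d[k][self.d_idx] * self.d_cov[k]
        return eta

    def logp_grad(self, theta):
        return _logp_grad_kernel(
            theta, self.y, self.home, self.X, self.m_idx, self.d_idx,
            self.m_cov, self.d_cov, self.M, self.D,
            self.spec.priors.fixed_sd ** 2, self.spec.priors.group_sd_rate)


def fit(design: pd.DataFrame, spec: ModelSpec,
        settings: McmcSettings = McmcSettings(), seed: int = 0) -> PosteriorDraws:
    """Sample the posterior of ``spec`` on ``design``.

    Deterministic given (settings, seed).  Emits a warning — and flags the
    result — if any chain diverges or split R-hat exceeds 1.01, but always
    returns the draws so the caller can inspect them.
    """
    post = _Posterior(design, spec)
    seqs = np.random.SeedSequence(seed).spawn(settings.chains)
    chain_draws, chain_stats = [], []
    for c in range(settings.chains):
        rng = np.random.default_rng(seqs[c])
        theta0 = 0.1 * rng.standard_normal(post.dim)
        theta0[-(post.Km + post.Kd):] = np.log(0.5)   # start group SDs at 0.5
        draws, stats = sample_chain(
            post.logp_grad, theta0, warmup=settings.warmup,
            samples=settings.samples, rng=rng,
            target_accept=settings.target_accept,
            max_depth=settings.max_depth)
        chain_draws.append(draws)
        chain_stats.append(stats)
    theta_ch = np.asarray(chain_draws)            # (chains, samples, dim)

    draws = _structured_draws(theta_ch, post)
    loglik = _pointwise_loglik(theta_ch, post)
    diagnostics = _diagnose(draws, chain_stats, settings)
    if diagnostics["divergences"] > 0 or diagnostics["max_rhat"] > RHAT_THRESHOLD:
        warnings.warn(
            f"model {spec.name!r}: convergence flagged "
            f"(divergences={diagnostics['divergences']}, "
            f"max R-hat={diagnostics['max_rhat']:.3f})", RuntimeWarning)
        diagnostics["converged"] = False
    else:
        diagnostics["converged"] = True
    return PosteriorDraws(spec=spec, draws=draws, loglik=loglik,
                          diagnostics=diagnostics,
                          manager_levels=post.manager_levels,
                          division_levels=post.division_levels,
                          obs_ids=design["obs_id"].to_numpy(), seed=seed)


def _structured_draws(theta_ch: np.ndarray, post: _Posterior) -> dict[str, np.ndarray]:
    C, S, _ = theta_ch.shape
    flat = theta_ch.reshape(C * S, -1)
    o = 0
    out: dict[str, np.ndarray] = {}
    out["alpha_home"] = flat[:, 0].reshape(C, S)
    out["alpha_away"] = flat[:, 1].reshape(C, S)
    o = 2
    for i, t in enumerate(post.spec.fixed_terms):
        out[f"beta_{t}"] = flat[:, o + i].reshape(C, S)
    o += post.F
    z_m = flat[:, o:o + post.Km * post.M].reshape(C, S, post.Km, post.M)
    o += post.Km * post.M
    z_d = flat[:, o:o + post.Kd * post.D].reshape(C, S, post.Kd, post.D)
    o += post.Kd * post.D
    tau_m = flat[:, o:o + post.Km].reshape(C, S, post.Km)
    o += post.Km
    tau_d = flat[:, o:o + post.Kd].reshape(C, S, post.Kd)
    for k, eff in enumerate(post.spec.manager_effects):
        sig = np.exp(tau_m[..., k])
        out[f"sigma_manager_{eff}"] = sig
        out[f"b_manager_{eff}"] = sig[..., None] * z_m[..., k, :]
    for k, eff in enumerate(post.spec.division_effects):
        sig = np.exp(tau_d[..., k])
        out[f"sigma_division_{eff}"] = sig
        out[f"b_division_{eff}"] = sig[..., None] * z_d[..., k, :]
    return out


def _pointwise_loglik(theta_ch: np.ndarray, post: _Posterior) -> np.ndarray:
    flat = theta_ch.reshape(-1, theta_ch.shape[-1])
    ll = np.empty((flat.shape[0], post.n))
    for s in range(flat.shape[0]):
        eta = post.eta(flat[s])
        ll[s] = post.y * eta - np.logaddexp(0.0, eta)
    return ll


def _diagnose(draws: dict[str, np.ndarray], chain_stats: list[dict],
              settings: McmcSettings) -> dict:
    scalars = {k: v for k, v in draws.items() if v.ndim == 2}
    idata = az.from_dict(posterior={k: v for k, v in scalars.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    max_rhat = float(max(rhat[v].values for v in rhat.data_vars))
    min_ess = float(min(ess[v].values for v in ess.data_vars))
    return {
        "divergences": int(sum(s["divergences"] for s in chain_stats)),
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "accept_rate": float(np.mean([s["accept_rate"] for s in chain_stats])),
        "chains": settings.chains,
        "samples": settings.samples,
    }


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_draws(fitted: PosteriorDraws, path) -> None:
    """Serialize a fitted model (draws, log-likelihoods, manifest) to .npz."""
    import json

    meta = {
        "spec": {
            "name": fitted.spec.name,
            "fixed_terms": list(fitted.spec.fixed_terms),
            "manager_slopes": list(fitted.spec.manager_slopes),
            "division_slopes": list(fitted.spec.division_slopes),
            "priors": {"fixed_sd": fitted.spec.priors.fixed_sd,
                       "group_sd_rate": fitted.spec.priors.group_sd_rate},
        },
        "diagnostics": fitted.diagnostics,
        "manager_levels": fitted.manager_levels,
        "division_levels": fitted.division_levels,
        "seed": fitted.seed,
    }
    arrays = {f"draw__{k}": v for k, v in fitted.draws.items()}
    np.savez_compressed(path, loglik=fitted.loglik,
                        obs_ids=fitted.obs_ids.astype(str),
                        meta=np.array(json.dumps(meta)), **arrays)


def load_draws(path) -> PosteriorDraws:
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        draws = {k[len("draw__"):]: z[k] for k in z.files
                 if k.startswith("draw__")}
        loglik = z["loglik"]
        obs_ids = z["obs_ids"]
    sp = meta["spec"]
    spec = ModelSpec(name=sp["name"], fixed_terms=tuple(sp["fixed_terms"]),
                     manager_slopes=tuple(sp["manager_slopes"]),
                     division_slopes=tuple(sp["division_slopes"]),
                     priors=Priors(**sp["priors"]))
    return PosteriorDraws(spec=spec, draws=draws, loglik=loglik,
                          diagnostics=meta["diagnostics"],
                          manager_levels=meta["manager_levels"],
                          division_levels=meta["division_levels"],
                          obs_ids=obs_ids, seed=meta["seed"])


# ---------------------------------------------------------------------------
# WAIC and model comparison
# ---------------------------------------------------------------------------

def waic(loglik: np.ndarray) -> dict[str, float | np.ndarray]:
    """Widely Applicable Information Criterion from an (S, N) log-likelihood.

    lppd_i  = log mean_s exp(ll_si)   (stable log-sum-exp)
    p_i     = var_s ll_si             (sample variance, ddof=1)
    WAIC    = -2 (sum lppd_i - sum p_i);  SE = sqrt(N var_i waic_i)
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need an (S, N) matrix with S >= 2")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log-likelihood entries")
    S, N = ll.shape
    lppd_i = np.logaddexp.reduce(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    return {
        "waic": float(waic_i.sum()),
        "p_waic": float(p_i.sum()),
        "se": float(np.sqrt(N * waic_i.var(ddof=1))) if N > 1 else 0.0,
        "pointwise": waic_i,
    }


def compare(models: list[PosteriorDraws]) -> pd.DataFrame:
    """WAIC comparison table: dWAIC, Akaike-style weights, SE and dSE."""
    if not models:
        raise ValueError("no models to compare")
    ref_ids = models[0].obs_ids
    for m in models[1:]:
        if m.n_obs != models[0].n_obs or not np.array_equal(m.obs_ids, ref_ids):
            raise ValueError("models fitted on different observation sets; "
                             "WAIC values are not comparable")
    stats = [waic(m.loglik) for m in models]
    waics = np.array([s["waic"] for s in stats])
    best = int(np.argmin(waics))
    d_waic = waics - waics[best]
    weights = np.exp(-0.5 * d_waic)
    weights /= weights.sum()
    d_se = []
    for i, s in enumerate(stats):
        if i == best:
            d_se.append(0.0)
        else:
            diff = s["pointwise"] - stats[best]["pointwise"]
            d_se.append(float(np.sqrt(diff.size * diff.var(ddof=1))))
    tbl = pd.DataFrame({
        "model": [m.spec.name for m in models],
        "waic": waics,
        "p_waic": [s["p_waic"] for s in stats],
        "d_waic": d_waic,
        "weight": weights,
        "se": [s["se"] for s in stats],
        "d_se": d_se,
    })
    return tbl.sort_values("waic", kind="mergesort").reset_index(drop=True)


def percentile_interval(x: np.ndarray, prob: float = INTERVAL_PROB
                        ) -> tuple[float, float]:
    """Central posterior interval (5.5%/94.5% quantiles at the default 0.89)."""
    lo = (1.0 - prob) / 2.0
    return (float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo)))


def coefficient_table(fitted: PosteriorDraws,
                      prob: float = INTERVAL_PROB) -> pd.DataFrame:
    """Posterior mean and percentile interval for every scalar parameter."""
    rows = []
    for name, arr in fitted.draws.items():
        if arr.ndim != 2:
            continue
        flat = arr.ravel()
        lo, hi = percentile_interval(flat, prob)
        rows.append({
            "parameter": name,
            "mean": float(flat.mean()),
            "lower": lo,
            "upper": hi,
            "excludes_zero": bool(lo > 0 or hi < 0),
        })
    return pd.DataFrame(rows)
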