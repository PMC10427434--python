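"""The four preregistered hypothesis tests and posterior-prediction quantities.

H1  model comparison by WAIC (see :func:`tacticlearn.hierarchical_models.compare`)
    plus coefficient intervals in the full model.
H2  the population:personal use ratio — the population-use coefficient
    divided by the personal-use coefficient, computed per posterior draw.
H3  varying-effect standard deviations on the real data versus the same
    model refitted on randomised (permuted) data.
H4  a quadratic (manager-level) regression of relative win rate on the
    use ratio; an adaptive trade-off predicts a negative quadratic term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, invgamma

from .match_data import FOCAL_DEFAULT, win_value
from .hierarchical_models import (INTERVAL_PROB, PosteriorDraws,
                                  percentile_interval)

NEAR_ZERO = 1e-8
RATIO_TRIM = 0.005      # fraction trimmed from each tail of the ratio draws


# ---------------------------------------------------------------------------
# H2: population:personal use ratio
# ---------------------------------------------------------------------------

def _ratio_summary(num: np.ndarray, den: np.ndarray, level: str) -> dict:
    near_zero = int(np.sum(np.abs(den) < NEAR_ZERO))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    finite = r[np.isfinite(r)]
    lo, hi = percentile_interval(finite)
    k = int(np.floor(RATIO_TRIM * finite.size))
    trimmed = np.sort(finite)[k:finite.size - k] if k > 0 else finite
    return {
        "level": level,
        "mean": float(finite.mean()),
        "trimmed_mean": float(trimmed.mean()),
        "ratio_of_means": float(num.mean() / den.mean()),
        "lower": lo,
        "upper": hi,
        "excludes_one": bool(lo > 1 or hi < 1),
        "n_near_zero_denominator": near_zero,
    }


def use_ratio(fitted: PosteriorDraws, scope: str = "global") -> pd.DataFrame:
    """Posterior of the population:personal use ratio.

    The ratio is formed draw by draw (never as a ratio of posterior means,
    which cannot yield the percentile interval); group scopes add that
    group's varying use-slope offsets to both coefficients before dividing.
    Draws with a near-zero denominator are retained but counted, and a
    0.5%-tail trimmed mean is reported alongside.
    """
    for term in ("beta_p_use", "beta_g_use"):
        if term not in fitted.draws:
            raise ValueError(f"model {fitted.spec.name!r} lacks {term}; "
                             "the ratio needs both use coefficients (full model)")
    num = fitted.stacked("beta_g_use")
    den = fitted.stacked("beta_p_use")
    if scope == "global":
        rows = [_ratio_summary(num, den, "global")]
    elif scope == "division":
        bg = fitted.stacked("b_division_g_use")
        bp = fitted.stacked("b_division_p_use")
        rows = [_ratio_summary(num + bg[:, j], den + bp[:, j], lvl)
                for j, lvl in enumerate(fitted.division_levels)]
    elif scope == "manager":
        bg = fitted.stacked("b_manager_g_use")
        bp = fitted.stacked("b_manager_p_use")
        rows = [_ratio_summary(num + bg[:, j], den + bp[:, j], lvl)
                for j, lvl in enumerate(fitted.manager_levels)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = pd.DataFrame(rows)
    frac_bad = out["n_near_zero_denominator"].sum() / (len(out) * num.size)
    if frac_bad > 0.05:
        warnings.warn(f"{frac_bad:.1%} of ratio draws have near-zero "
                      "denominators; summaries may be unstable", RuntimeWarning)
    return out


# ---------------------------------------------------------------------------
# Fig-2-style prediction curves
# ---------------------------------------------------------------------------

def prediction_curves(fitted: PosteriorDraws, which: str = "personal",
                      win_offset: float = 0.0,
                      use_grid: np.ndarray | None = None,
                      home: bool = True,
                      prob: float = INTERVAL_PROB) -> pd.DataFrame:
    """Posterior-predictive P(focal) versus the use predictor.

    Evaluated for the average manager and division (varying offsets zero)
    with the matching win-rate predictor fixed at ``win_offset`` and every
    other predictor at 0, so only the use, win-rate and use x win-rate
    terms contribute.
    """
    if which not in ("personal", "population"):
        raise ValueError("which must be 'personal' or 'population'")
    p = "p" if which == "personal" else "g"
    use = fitted.stacked(f"beta_{p}_use")
    win = fitted.stacked(f"beta_{p}_win")
    inter = fitted.stacked(f"beta_{p}_use_x_{p}_win")
    alpha = fitted.stacked("alpha_home" if home else "alpha_away")
    grid = np.linspace(-0.5, 0.5, 21) if use_grid is None else np.asarray(use_grid)
    rows = []
    for u in grid:
        eta = alpha + use * u + win * win_offset + inter * u * win_offset
        pr = expit(eta)
        lo, hi = percentile_interval(pr, prob)
        rows.append({"use": float(u), "mean": float(pr.mean()),
                     "lower": lo, "upper": hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# H3: randomisation null for varying-effect SDs
# ---------------------------------------------------------------------------

def randomize_dataset(observations: pd.DataFrame, seed: int,
                      stratify: str = "division_season",
                      focal: str = FOCAL_DEFAULT) -> pd.DataFrame:
    """Permute formations and outcomes across observations.

    Formation labels and (won, drew) outcome pairs are permuted
    independently of each other — within each division-season stratum by
    default, or globally — preserving marginal frequencies while severing
    any manager-level association.  ``is_focal`` and ``opponent_formation``
    are rebuilt for consistency.  Deterministic given ``seed``.
    """
    if stratify not in ("division_season", "global"):
        raise ValueError(f"unknown stratification {stratify!r}")
    rng = np.random.default_rng(seed)
    out = observations.copy().reset_index(drop=True)
    if stratify == "global":
        groups = [np.arange(len(out))]
    else:
        groups = [np.asarray(ix) for _, ix in
                  sorted(out.groupby(["division", "season"]).indices.items())]
    formations = out["formation"].to_numpy().copy()
    won = out["won"].to_numpy().copy()
    drew = out["drew"].to_numpy().copy()
    for ix in groups:
        formations[ix] = formations[rng.permutation(ix)]
        perm = rng.permutation(ix)
        won[ix], drew[ix] = won[perm], drew[perm]
    out["formation"] = formations
    out["won"], out["drew"] = won, drew
    out["is_focal"] = out["formation"] == focal
    partner = out.set_index(["match_id", "is_home"])["formation"]
    out["opponent_formation"] = [
        partner.get((m, not h), f) for m, h, f in
        zip(out["match_id"], out["is_home"], out["formation"])]
    return out


@dataclass
class SdContrast:
    table: pd.DataFrame       # one row per varying-effect SD
    diff_draws: dict[str, np.ndarray]


def varying_sd_comparison(real: PosteriorDraws, randomized: PosteriorDraws,
                          effects: list[str] | None = None) -> SdContrast:
    """Real-minus-randomised posterior contrast of varying-effect SDs.

    Draw-by-draw differences of the group standard deviations for the use
    slopes (manager and division level by default), summarised with 89%
    intervals; a positive difference indicates more between-group strategy
    variation than random assignment of formations and outcomes produces.
    """
    if real.spec != randomized.spec:
        raise ValueError("real and randomized fits use different model specs")
    if effects is None:
        effects = [e for e in ("sigma_manager_p_use", "sigma_manager_g_use",
                               "sigma_division_p_use", "sigma_division_g_use")
                   if e in real.draws]
    rows, diffs = [], {}
    for eff in effects:
        a = real.stacked(eff)
        b = randomized.stacked(eff)
        s = min(a.size, b.size)
        d = a[:s] - b[:s]
        lo, hi = percentile_interval(d)
        diffs[eff] = d
        rows.append({
            "effect": eff,
            "real_sd": float(a.mean()),
            "randomized_sd": float(b.mean()),
            "difference": float(d.mean()),
            "lower": lo,
            "upper": hi,
            "reliably_positive": bool(lo > 0),
        })
    return SdContrast(table=pd.DataFrame(rows), diff_draws=diffs)


# ---------------------------------------------------------------------------
# H4: quadratic manager-level success model
# ---------------------------------------------------------------------------

def manager_table(fitted: PosteriorDraws, observations: pd.DataFrame,
                  convention: str = "win", min_games: int = 1) -> pd.DataFrame:
    """One row per manager: relative win rate and use-ratio estimate.

    Relative win rate is the manager's per-game success value centred on
    the division-season average and then averaged over all their games.
    The ratio estimate is the trimmed posterior mean of the manager-scope
    population:personal ratio.
    """
    obs = observations.copy()
    obs["_wv"] = win_value(obs, convention)
    obs["_rel"] = obs["_wv"] - obs.groupby(["division", "season"])["_wv"].transform("mean")
    per_mgr = obs.groupby("manager").agg(
        games=("_wv", "size"), rel_win_rate=("_rel", "mean"))
    ratios = use_ratio(fitted, scope="manager").set_index("level")
    tbl = per_mgr.join(ratios[["trimmed_mean", "mean"]], how="inner")
    tbl = tbl.rename(columns={"trimmed_mean": "ratio", "mean": "ratio_mean"})
    tbl = tbl[tbl["games"] >= min_games]
    return tbl.reset_index().rename(columns={"index": "manager"})


@dataclass
class QuadraticFit:
    table: pd.DataFrame            # rows a, b1, b2, sigma with mean/interval
    coef_draws: np.ndarray         # (S, 3)
    sigma_draws: np.ndarray        # (S,)
    b2_reliably_negative: bool     # the adaptive-trade-off verdict
    n_managers: int


def quadratic_winrate_model(manager_tbl: pd.DataFrame, n_draws: int = 4000,
                            seed: int = 0,
                            prior_scale: float = 100.0,
                            sigma_prior: tuple[float, float] = (2.0, 0.002),
                            ) -> QuadraticFit:
    """Bayesian quadratic regression of relative win rate on the use ratio.

        win_rate_m ~ Normal(a + b1 r_m + b2 r_m^2, sigma)

    Conjugate normal-inverse-gamma posterior sampled exactly: coefficients
    have a Normal(0, sigma^2 prior_scale^2) prior and sigma^2 an
    InvGamma prior, weak enough that estimates track least squares.  The
    trade-off hypothesis is supported when b2's 89% interval lies entirely
    below zero.
    """
    if len(manager_tbl) < 3:
        raise ValueError("need at least 3 managers for the quadratic model")
    r = manager_tbl["ratio"].to_numpy(dtype=float)
    y = manager_tbl["rel_win_rate"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(r), r, r ** 2])
    n, k = X.shape
    v0_inv = np.eye(k) / prior_scale ** 2
    vn_inv = v0_inv + X.T @ X
    vn = np.linalg.inv(vn_inv)
    mn = vn @ (X.T @ y)
    a0, b0 = sigma_prior
    an = a0 + 0.5 * n
    bn = b0 + 0.5 * float(y @ y - mn @ vn_inv @ mn)
    rng = np.random.default_rng(seed)
    sigma2 = invgamma.rvs(an, scale=bn, size=n_draws, random_state=rng)
    chol = np.linalg.cholesky(vn)
    z = rng.standard_normal((n_draws, k))
    coef = mn + np.sqrt(sigma2)[:, None] * (z @ chol.T)
    sigma = np.sqrt(sigma2)
    rows = []
    for name, d in zip(("a", "b1", "b2"), coef.T):
        lo, hi = percentile_interval(d)
        rows.append({"parameter": name, "mean": float(d.mean()),
                     "lower": lo, "upper": hi})
    lo_s, hi_s = percentile_interval(sigma)
    rows.append({"parameter": "sigma", "mean": float(sigma.mean()),
                 "lower": lo_s, "upper": hi_s})
    tbl = pd.DataFrame(rows)
    b2_lo, b2_hi = tbl.loc[tbl["parameter"] == "b2", ["lower", "upper"]].iloc[0]
    return QuadraticFit(table=tbl, coef_draws=coef, sigma_draws=sigma,
                        b2_reliably_negative=bool(b2_hi < 0), n_managers=n)


# ---------------------------------------------------------------------------
# Fig-5-style joint posteriors
# ---------------------------------------------------------------------------

def manager_joint_posteriors(fitted: PosteriorDraws, managers: list[str],
                             prob: float = 0.80) -> dict[str, dict]:
    """Per-manager bivariate draws of (personal reliance, social reliance).

    Personal reliance is beta_p_use plus the manager's p_use offset; social
    reliance likewise for g_use.  The covariance ellipse containing
    ``prob`` of a matching Gaussian is returned as (width, height, angle).
    """
    bp = fitted.stacked("b_manager_p_use")
    bg = fitted.stacked("b_manager_g_use")
    beta_p = fitted.stacked("beta_p_use")
    beta_g = fitted.stacked("beta_g_use")
    out = {}
    for m in managers:
        if m not in fitted.manager_levels:
            raise KeyError(f"unknown manager {m!r}")
        j = fitted.manager_levels.index(m)
        draws = np.column_stack([beta_p + bp[:, j], beta_g + bg[:, j]])
        center = draws.mean(axis=0)
        cov = np.cov(draws.T)
        evals, evecs = np.linalg.eigh(cov)
        scale = np.sqrt(chi2.ppf(prob, df=2))
        angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
        out[m] = {
            "draws": draws,
            "center": center,
            "cov": cov,
            "ellipse": {
                "width": float(2 * scale * np.sqrt(evals[-1])),
                "height": float(2 * scale * np.sqrt(evals[0])),
                "angle_deg": angle,
            },
        }
    return out
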