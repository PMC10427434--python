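"""Independent reference implementations used only to cross-check the package.

Deliberately naive: nested loops over observations and dates, no indexing
structures, no shared code with the library paths they validate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_design(observations: pd.DataFrame, x_days: int,
                       focal: str = "4231", exclude_own_team: bool = False,
                       season_starts: dict | None = None) -> pd.DataFrame:
    """Moving-window predictors by exhaustive pairwise date comparison."""
    obs = observations.reset_index(drop=True)
    n = len(obs)
    win = [1.0 if w else 0.0 for w in obs["won"]]
    foc = [f == focal for f in obs["formation"]]

    starts = {}
    for i in range(n):
        key = (obs["division"][i], obs["season"][i])
        d = obs["match_date"][i]
        if key not in starts or d < starts[key]:
            starts[key] = d
    if season_starts:
        starts.update(season_starts)

    strength = {}
    for key in {(obs["division"][i], obs["season"][i]) for i in range(n)}:
        teams = {}
        for i in range(n):
            if (obs["division"][i], obs["season"][i]) == key:
                teams.setdefault(obs["team"][i], []).append(win[i])
        means = {t: sum(v) / len(v) for t, v in teams.items()}
        centre = sum(means.values()) / len(means)
        for t, m in means.items():
            strength[key + (t,)] = m - centre

    rows = []
    for i in range(n):
        div, ssn = obs["division"][i], obs["season"][i]
        di = obs["match_date"][i]
        if (di - starts[(div, ssn)]).days < x_days:
            continue
        personal, population, pop_all = [], [], []
        for j in range(n):
            if (obs["division"][j], obs["season"][j]) != (div, ssn):
                continue
            lag = (di - obs["match_date"][j]).days
            if not (1 <= lag <= x_days):
                continue
            pop_all.append(j)
            if not (exclude_own_team and obs["team"][j] == obs["team"][i]):
                population.append(j)
            if obs["manager"][j] == obs["manager"][i]:
                personal.append(j)

        def use(ix):
            return sum(1 for j in ix if foc[j]) / len(ix) - 0.5 if ix else np.nan

        def windiff(ix):
            f = [j for j in ix if foc[j]]
            nf = [j for j in ix if not foc[j]]
            if not f or not nf:
                return np.nan
            return (sum(win[j] for j in f) / len(f)
                    - sum(win[j] for j in nf) / len(nf))

        o_win = (sum(win[j] for j in personal) / len(personal)
                 - sum(win[j] for j in pop_all) / len(pop_all)
                 if personal and pop_all else np.nan)
        vals = {"p_use": use(personal), "p_win": windiff(personal),
                "g_use": use(population), "g_win": windiff(population),
                "o_win": o_win}
        vals = {k: (0.0 if isinstance(v, float) and np.isnan(v) else v)
                for k, v in vals.items()}
        rows.append({
            "obs_id": obs["obs_id"][i],
            **vals,
            "p_use_x_p_win": vals["p_use"] * vals["p_win"],
            "p_use_x_o_win": vals["p_use"] * vals["o_win"],
            "g_use_x_g_win": vals["g_use"] * vals["g_win"],
            "g_use_x_o_win": vals["g_use"] * vals["o_win"],
            "team_strength": strength[(div, ssn, obs["team"][i])],
            "n_personal_games": len(personal),
            "n_population_games": len(population),
        })
    return pd.DataFrame(rows)


def naive_waic(loglik: np.ndarray) -> tuple[float, float, float]:
    """Two-pass WAIC: (waic, p_waic, se), no log-sum-exp shortcuts."""
    S, N = loglik.shape
    lppd_i, p_i = [], []
    for i in range(N):
        col = loglik[:, i]
        m = max(col)
        lppd_i.append(m + np.log(sum(np.exp(c - m) for c in col) / S))
        mean = sum(col) / S
        p_i.append(sum((c - mean) ** 2 for c in col) / (S - 1))
    waic_i = [-2 * (l - p) for l, p in zip(lppd_i, p_i)]
    waic = sum(waic_i)
    mean_w = waic / N
    var_w = sum((w - mean_w) ** 2 for w in waic_i) / (N - 1)
    return waic, sum(p_i), float(np.sqrt(N * var_w))
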