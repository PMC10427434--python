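"""Moving-window predictor construction.

For every formation observation the predictors summarise two information
sources available to the manager on match day, computed from all games in
the same division and season during the preceding X calendar days (never
including the match day itself):

personal (individual learning)
    a. ``p_use``   — manager's focal-use proportion, centred on 0.5
    b. ``p_win``   — manager's focal win rate minus their non-focal win rate
    c. ``p_use_x_p_win`` — a x b
    d. ``p_use_x_o_win`` — a x manager's overall win rate, the latter centred
       on the all-manager window win rate of the division-season

population (social learning)
    e. ``g_use``   — division-wide focal-use proportion, centred on 0.5
    f. ``g_win``   — division-wide focal minus non-focal win rate
    g. ``g_use_x_g_win`` — e x f
    h. ``g_use_x_o_win`` — e x the same centred overall win rate as (d)

plus controls: home/away indicator, and team strength (the team's
full-season win proportion centred on the division-season team mean —
deliberately using future games, as a season-constant ability proxy).
Windows reset at each season start, so observations in a season's first X
days are not modelled as outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .match_data import FOCAL_DEFAULT, win_value

#: design-matrix predictor columns, in model order
PREDICTOR_TERMS = [
    "p_use", "p_win", "p_use_x_p_win", "p_use_x_o_win",
    "g_use", "g_win", "g_use_x_g_win", "g_use_x_o_win",
]
CONTROL_TERMS = ["team_strength"]
OPPONENT_TERMS = ["opp_strength", "opp_focal"]


@dataclass
class WindowConfig:
    """Options for building the design matrix."""

    x_days: int = 30                        # window length in calendar days
    exclude_own_team: bool = False          # drop own team from population sets
    include_opponent_controls: bool = False
    focal: str = FOCAL_DEFAULT
    win_convention: str = "win"             # "win" or "points" (draw = 0.5)

    def __post_init__(self):
        if self.x_days <= 0:
            raise ValueError("window length must be positive")


# ---------------------------------------------------------------------------
# scalar window statistics (shared with the synthetic-league generator)
# ---------------------------------------------------------------------------

def use_proportion(is_focal: np.ndarray) -> float:
    """Focal-use proportion centred on 0.5; NaN for an empty set."""
    is_focal = np.asarray(is_focal, dtype=bool)
    if is_focal.size == 0:
        return np.nan
    return float(is_focal.mean() - 0.5)


def winrate_difference(is_focal: np.ndarray, wins: np.ndarray) -> float:
    """Focal win rate minus non-focal win rate; NaN unless both sets non-empty."""
    is_focal = np.asarray(is_focal, dtype=bool)
    wins = np.asarray(wins, dtype=float)
    n_focal = int(is_focal.sum())
    if n_focal == 0 or n_focal == is_focal.size:
        return np.nan
    return float(wins[is_focal].mean() - wins[~is_focal].mean())


def overall_winrate_centered(personal_wins: np.ndarray,
                             baseline_wins: np.ndarray) -> float:
    """Manager's window win rate over all formations minus the all-manager rate."""
    personal_wins = np.asarray(personal_wins, dtype=float)
    baseline_wins = np.asarray(baseline_wins, dtype=float)
    if personal_wins.size == 0 or baseline_wins.size == 0:
        return np.nan
    return float(personal_wins.mean() - baseline_wins.mean())


# ---------------------------------------------------------------------------
# window membership
# ---------------------------------------------------------------------------

def window_games(obs: pd.Series, observations: pd.DataFrame, x_days: int,
                 exclude_own_team: bool = False
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Personal and population game sets for one observation.

    Both sets are restricted to the observation's division and season and
    to dates strictly before the match day but at most ``x_days`` earlier.
    """
    same = observations[(observations["division"] == obs["division"])
                        & (observations["season"] == obs["season"])]
    lag = (obs["match_date"] - same["match_date"]).map(lambda d: d.days)
    in_window = same[(lag >= 1) & (lag <= x_days)]
    personal = in_window[in_window["manager"] == obs["manager"]]
    population = in_window
    if exclude_own_team:
        population = population[population["team"] != obs["team"]]
    return personal, population


def season_team_strength(observations: pd.DataFrame,
                         convention: str = "win") -> pd.DataFrame:
    """Season-long team win proportion centred on the division-season team mean."""
    obs = observations.copy()
    obs["_wv"] = win_value(obs, convention)
    per_team = (obs.groupby(["division", "season", "team"])["_wv"]
                .mean().rename("raw").reset_index())
    per_team["team_strength"] = (per_team["raw"] - per_team.groupby(
        ["division", "season"])["raw"].transform("mean"))
    return per_team[["division", "season", "team", "team_strength"]]


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design(observations: pd.DataFrame, config: WindowConfig,
                 season_starts: dict[tuple[str, str], date] | None = None
                 ) -> pd.DataFrame:
    """Build the predictor table for every eligible observation.

    Eligibility: at least ``x_days`` days must have elapsed since the
    season start (taken from ``season_starts`` keyed by (division, season),
    defaulting to the division-season's first match date), so every outcome
    has a full-length window behind it.  Window statistics that are
    undefined — a manager with no window games, or no focal/non-focal split
    — are imputed with 0, the no-information value on the centred scales;
    ``n_personal_games`` / ``n_population_games`` record the information
    actually available.  Interaction columns are exact products of their
    (imputed) parts.
    """
    obs = observations.reset_index(drop=True)
    focal = obs["formation"].to_numpy() == config.focal
    wv = win_value(obs, config.win_convention)
    strength = season_team_strength(obs, config.win_convention)
    smap = {(d, s, t): v for d, s, t, v in strength.itertuples(index=False)}

    rows: list[dict] = []
    for (div, ssn), grp in obs.groupby(["division", "season"], sort=True):
        idx = grp.index.to_numpy()
        ords = np.array([d.toordinal() for d in grp["match_date"]])
        managers = grp["manager"].to_numpy()
        teams = grp["team"].to_numpy()
        g_focal, g_wv = focal[idx], wv[idx]
        if season_starts and (div, ssn) in season_starts:
            start_ord = season_starts[(div, ssn)].toordinal()
        else:
            start_ord = int(ords.min())

        for day in np.unique(ords):
            if day - start_ord < config.x_days:
                continue
            wmask = (ords >= day - config.x_days) & (ords < day)
            pop_all_wv = g_wv[wmask]
            today = np.flatnonzero(ords == day)
            for j in today:
                pmask = wmask & (managers == managers[j])
                gmask = wmask if not config.exclude_own_team else (
                    wmask & (teams != teams[j]))
                o_win = overall_winrate_centered(g_wv[pmask], pop_all_wv)
                row = {
                    "obs_id": obs["obs_id"].iloc[idx[j]],
                    "p_use": use_proportion(g_focal[pmask]),
                    "p_win": winrate_difference(g_focal[pmask], g_wv[pmask]),
                    "g_use": use_proportion(g_focal[gmask]),
                    "g_win": winrate_difference(g_focal[gmask], g_wv[gmask]),
                    "o_win": o_win,
                    "n_personal_games": int(pmask.sum()),
                    "n_population_games": int(gmask.sum()),
                }
                rows.append(row)

    design = pd.DataFrame(rows)
    if design.empty:
        return design
    for col in ["p_use", "p_win", "g_use", "g_win", "o_win"]:
        design[f"{col}_imputed"] = design[col].isna()
        design[col] = design[col].fillna(0.0)
    design["p_use_x_p_win"] = design["p_use"] * design["p_win"]
    design["p_use_x_o_win"] = design["p_use"] * design["o_win"]
    design["g_use_x_g_win"] = design["g_use"] * design["g_win"]
    design["g_use_x_o_win"] = design["g_use"] * design["o_win"]

    meta = obs.set_index("obs_id")
    design = design.set_index("obs_id")
    design["is_home"] = meta["is_home"]
    design["is_focal"] = meta["formation"] == config.focal
    design["manager"] = meta["manager"]
    design["division"] = meta["division"]
    design["season"] = meta["season"]
    design["match_date"] = meta["match_date"]
    design["team_strength"] = [
        smap[(meta.loc[o, "division"], meta.loc[o, "season"], meta.loc[o, "team"])]
        for o in design.index]
    if config.include_opponent_controls:
        design["opp_strength"] = [
            smap.get((meta.loc[o, "division"], meta.loc[o, "season"],
                      meta.loc[o, "opponent_team"]), 0.0)
            for o in design.index]
        design["opp_focal"] = (meta.loc[design.index, "opponent_formation"]
                               == config.focal).astype(float)

    order = (PREDICTOR_TERMS + ["o_win"] + CONTROL_TERMS
             + (OPPONENT_TERMS if config.include_opponent_controls else [])
             + ["is_home", "is_focal", "manager", "division", "season",
                "match_date", "n_personal_games", "n_population_games"]
             + [c for c in design.columns if c.endswith("_imputed")])
    return design[order].reset_index()


def window_size_summary(design: pd.DataFrame) -> dict[str, float]:
    """Mean personal and population window sizes over eligible observations."""
    return {
        "mean_personal_games": float(design["n_personal_games"].mean()),
        "mean_population_games": float(design["n_population_games"].mean()),
    }
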