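"""Match-level data ingestion, cleaning and reshaping.

The unit of raw data is one game between a home and an away side; the unit
of analysis is one *formation observation* — one team-side of one game, so
every match contributes two observations.  This module reads the match CSV,
harmonizes manager-name spellings, attaches seasons from a per-division
calendar, compresses the Bundesliga winter break so that moving-window
predictors always find prior games, expands matches to observations, and
computes the descriptive formation-frequency summaries.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

FOCAL_DEFAULT = "4231"

RESULT_HOME, RESULT_DRAW, RESULT_AWAY = "home_win", "draw", "away_win"
RESULTS = (RESULT_HOME, RESULT_DRAW, RESULT_AWAY)

#: canonical match-table columns
MATCH_COLUMNS = [
    "match_id", "match_date", "division", "season",
    "home_team", "away_team", "home_manager", "away_manager",
    "home_formation", "away_formation", "result",
]

#: canonical observation-table columns (two rows per match)
OBS_COLUMNS = [
    "obs_id", "match_id", "match_date", "division", "season",
    "team", "manager", "opponent_team", "opponent_manager",
    "formation", "opponent_formation", "is_focal",
    "won", "drew", "is_home",
]

#: default mapping from raw CSV headers to canonical names
DEFAULT_COLUMN_MAP = {
    "date": "match_date",
    "league": "division",
    "division": "division",
    "season": "season",
    "home_team": "home_team",
    "away_team": "away_team",
    "home_manager": "home_manager",
    "away_manager": "away_manager",
    "home_formation": "home_formation",
    "away_formation": "away_formation",
    "result": "result",
    "home_goals": "home_goals",
    "away_goals": "away_goals",
}

REQUIRED_RAW = [
    "match_date", "division", "home_team", "away_team",
    "home_manager", "away_manager", "home_formation", "away_formation",
]


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class RowParseError(ValueError):
    """A row could not be parsed; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class SeasonAssignmentError(ValueError):
    """A match date falls outside every season window of its division."""


# ---------------------------------------------------------------------------
# season calendar
# ---------------------------------------------------------------------------

@dataclass
class SeasonCalendar:
    """Official season windows per division, plus mid-season break intervals.

    ``seasons`` maps division -> season label -> (start, end) dates;
    ``breaks`` maps division -> season label -> (break_start, break_end).
    Breaks are declared only for divisions with a long winter pause
    (the Bundesliga); the pause is compressed to ``break_target_days`` so
    that day-window predictors always see prior games.
    """

    seasons: dict[str, dict[str, tuple[date, date]]]
    breaks: dict[str, dict[str, tuple[date, date]]] = field(default_factory=dict)
    break_target_days: int = 10

    @classmethod
    def from_mapping(cls, raw: dict) -> "SeasonCalendar":
        def _d(v):
            return v if isinstance(v, date) else date.fromisoformat(str(v))

        seasons = {
            div: {s: (_d(w["start"]), _d(w["end"])) for s, w in body["seasons"].items()}
            for div, body in raw["divisions"].items()
        }
        breaks = {
            div: {s: (_d(b["start"]), _d(b["end"]))
                  for s, b in body.get("breaks", {}).items()}
            for div, body in raw["divisions"].items()
            if body.get("breaks")
        }
        return cls(seasons=seasons, breaks=breaks,
                   break_target_days=int(raw.get("break_target_days", 10)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SeasonCalendar":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "SeasonCalendar":
        """The bundled calendar for the five top European leagues, 2012/13–2016/17."""
        ref = importlib.resources.files("tacticlearn") / "season_calendars.yml"
        return cls.from_mapping(yaml.safe_load(ref.read_text()))

    def season_of(self, division: str, when: date) -> str:
        windows = self.seasons.get(division)
        if not windows:
            raise SeasonAssignmentError(f"division {division!r} not in calendar")
        for label, (start, end) in windows.items():
            if start <= when <= end:
                return label
        raise SeasonAssignmentError(
            f"date {when} outside every season window of {division!r}")

    def season_start(self, division: str, season: str) -> date:
        return self.seasons[division][season][0]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_matches(path: str | Path, column_map: dict[str, str] | None = None,
                 date_format: str | None = None) -> pd.DataFrame:
    """Read a match CSV into the canonical match table.

    One row per game.  The ``result`` column is taken verbatim if present
    (values ``home_win`` / ``draw`` / ``away_win``) and otherwise derived
    from ``home_goals`` / ``away_goals``.  Dates are parsed strictly; an
    unparseable date raises :class:`RowParseError` with the row index.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    renamed = raw.rename(columns={c: cmap[c] for c in raw.columns if c in cmap})

    for col in REQUIRED_RAW:
        if col not in renamed.columns:
            raise SchemaError(f"missing required column {col!r}")
    if "result" not in renamed.columns and not (
            "home_goals" in renamed.columns and "away_goals" in renamed.columns):
        raise SchemaError("need either a 'result' column or goal columns")

    out = pd.DataFrame(index=renamed.index)
    dates = pd.to_datetime(renamed["match_date"], format=date_format, errors="coerce")
    if dates.isna().any():
        bad = int(np.flatnonzero(dates.isna().to_numpy())[0])
        raise RowParseError(bad, f"unparseable date {renamed['match_date'].iloc[bad]!r}")
    out["match_id"] = [f"m{i:06d}" for i in range(len(renamed))]
    out["match_date"] = dates.dt.date
    out["division"] = renamed["division"].str.strip()
    out["season"] = renamed["season"].str.strip() if "season" in renamed.columns else pd.NA
    for col in ["home_team", "away_team", "home_manager", "away_manager"]:
        out[col] = renamed[col].str.strip()
    for col in ["home_formation", "away_formation"]:
        out[col] = renamed[col].str.strip()
        if (out[col] == "").any():
            bad = int(np.flatnonzero((out[col] == "").to_numpy())[0])
            raise RowParseError(bad, f"empty {col}")

    if "result" in renamed.columns and (renamed["result"].str.strip() != "").all():
        res = renamed["result"].str.strip()
        unknown = ~res.isin(RESULTS)
        if unknown.any():
            bad = int(np.flatnonzero(unknown.to_numpy())[0])
            raise RowParseError(bad, f"unknown result {res.iloc[bad]!r}")
        out["result"] = res
    else:
        hg = pd.to_numeric(renamed["home_goals"], errors="coerce")
        ag = pd.to_numeric(renamed["away_goals"], errors="coerce")
        if hg.isna().any() or ag.isna().any():
            bad = int(np.flatnonzero((hg.isna() | ag.isna()).to_numpy())[0])
            raise RowParseError(bad, "unparseable goal count")
        out["result"] = np.select([hg > ag, hg < ag], [RESULT_HOME, RESULT_AWAY],
                                  default=RESULT_DRAW)
    return out[MATCH_COLUMNS]


def harmonize_managers(matches: pd.DataFrame,
                       alias_map: dict[str, str]) -> pd.DataFrame:
    """Replace manager-name spelling variants with canonical names.

    Unknown names pass through unchanged; idempotent as long as canonical
    names are not themselves aliases.
    """
    out = matches.copy()
    for col in ("home_manager", "away_manager"):
        out[col] = out[col].map(lambda m: alias_map.get(m, m))
    return out


def assign_seasons_and_breaks(matches: pd.DataFrame,
                              calendar: SeasonCalendar) -> pd.DataFrame:
    """Attach season labels from the calendar and compress winter breaks.

    For every division with a declared break, all matches of that season
    dated on/after the break end are shifted earlier so the idle gap that
    spans the break becomes exactly ``calendar.break_target_days`` days.
    Relative order and all other inter-match gaps are preserved.
    """
    out = matches.copy()
    need = out["season"].isna() | (out["season"].astype(str).str.strip() == "")
    if need.any():
        seasons = out["season"].astype(object)
        for i in np.flatnonzero(need.to_numpy()):
            seasons.iloc[i] = calendar.season_of(out["division"].iloc[i],
                                                 out["match_date"].iloc[i])
        out["season"] = seasons
    # validate all dates sit inside their declared season window
    for i in range(len(out)):
        div, ssn, d = out["division"].iloc[i], out["season"].iloc[i], out["match_date"].iloc[i]
        windows = calendar.seasons.get(div, {})
        if ssn in windows:
            start, end = windows[ssn]
            if not (start <= d <= end):
                raise SeasonAssignmentError(
                    f"match {out['match_id'].iloc[i]} on {d} outside {div} {ssn} window")

    for div, season_breaks in calendar.breaks.items():
        for ssn, (bstart, bend) in season_breaks.items():
            mask = (out["division"] == div) & (out["season"] == ssn)
            if not mask.any():
                continue
            dates = out.loc[mask, "match_date"]
            before = dates[dates < bstart]
            after = dates[dates >= bstart]
            if before.empty or after.empty:
                continue
            gap = (after.min() - before.max()).days
            shift = gap - calendar.break_target_days
            if shift > 0:
                shifted = dates.map(
                    lambda d: d - timedelta(days=shift) if d >= bstart else d)
                out.loc[mask, "match_date"] = shifted
    return out


# ---------------------------------------------------------------------------
# reshaping and summaries
# ---------------------------------------------------------------------------

def to_observations(matches: pd.DataFrame,
                    focal: str = FOCAL_DEFAULT) -> pd.DataFrame:
    """Expand each match into its two team-side formation observations."""
    halves = []
    for side, opp in (("home", "away"), ("away", "home")):
        half = pd.DataFrame({
            "obs_id": matches["match_id"] + "_" + side,
            "match_id": matches["match_id"],
            "match_date": matches["match_date"],
            "division": matches["division"],
            "season": matches["season"],
            "team": matches[f"{side}_team"],
            "manager": matches[f"{side}_manager"],
            "opponent_team": matches[f"{opp}_team"],
            "opponent_manager": matches[f"{opp}_manager"],
            "formation": matches[f"{side}_formation"],
            "opponent_formation": matches[f"{opp}_formation"],
            "won": (matches["result"] == f"{side}_win"),
            "drew": (matches["result"] == RESULT_DRAW),
            "is_home": side == "home",
        })
        halves.append(half)
    obs = pd.concat(halves, ignore_index=True)
    obs["is_focal"] = obs["formation"] == focal
    obs = obs.sort_values(["match_date", "match_id", "is_home"],
                          ascending=[True, True, False], kind="mergesort")
    return obs[OBS_COLUMNS].reset_index(drop=True)


def descriptive_summary(observations: pd.DataFrame,
                        focal: str = FOCAL_DEFAULT) -> pd.DataFrame:
    """Formation-frequency table, overall and per (division, season).

    Returns one row per (stratum, formation) with the observation count of
    the stratum, the formation's share within it, and a focal flag; the
    overall stratum is labelled division='all', season='all'.  Shares sum
    to 1 within each stratum.
    """
    if observations.empty:
        return pd.DataFrame(columns=["division", "season", "formation",
                                     "n_obs", "count", "share", "is_focal"])

    def _stratum(df: pd.DataFrame, div: str, ssn: str) -> pd.DataFrame:
        counts = df["formation"].value_counts()
        return pd.DataFrame({
            "division": div, "season": ssn,
            "formation": counts.index,
            "n_obs": len(df),
            "count": counts.to_numpy(),
            "share": counts.to_numpy() / len(df),
            "is_focal": counts.index == focal,
        })

    parts = [_stratum(observations, "all", "all")]
    for (div, ssn), grp in observations.groupby(["division", "season"], sort=True):
        parts.append(_stratum(grp, div, ssn))
    return pd.concat(parts, ignore_index=True)


def win_value(observations: pd.DataFrame, convention: str = "win") -> np.ndarray:
    """Per-observation success value: 1 for a win, draws per convention.

    ``"win"`` counts draws as 0 ("proportion of games won" literally);
    ``"points"`` credits draws 0.5 (a point-share reading of 'win rate').
    """
    if convention == "win":
        return observations["won"].to_numpy(dtype=float)
    if convention == "points":
        return (observations["won"].to_numpy(dtype=float)
                + 0.5 * observations["drew"].to_numpy(dtype=float))
    raise ValueError(f"unknown win convention {convention!r}")


def manager_usage_summary(observations: pd.DataFrame,
                          focal: str = FOCAL_DEFAULT,
                          division: str | None = None) -> pd.DataFrame:
    """Per-manager game counts and focal-formation usage share."""
    obs = observations if division is None else observations[
        observations["division"] == division]
    grp = obs.groupby("manager")
    out = pd.DataFrame({
        "games": grp.size(),
        "focal_games": grp["is_focal"].sum(),
    })
    out["focal_share"] = out["focal_games"] / out["games"]
    return out.reset_index()


def manager_win_rates(observations: pd.DataFrame,
                      convention: str = "win") -> pd.DataFrame:
    """Per-manager overall win rate across every game they managed."""
    obs = observations.copy()
    obs["_wv"] = win_value(obs, convention)
    grp = obs.groupby("manager")
    out = pd.DataFrame({"games": grp.size(), "win_rate": grp["_wv"].mean()})
    return out.reset_index()
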