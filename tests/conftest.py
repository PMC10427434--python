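import numpy as np
import pandas as pd
import pytest

import tacticlearn as tl
from tacticlearn.hierarchical_models import McmcSettings, ModelSpec, fit


@pytest.fixture(scope="session")
def desk_sim():
    """Small two-division league with nonzero use effects."""
    cfg = tl.SimulationConfig(
        beta={**{t: 0.0 for t in tl.synthetic_league.ALL_BETA_TERMS},
              "p_use": 0.8, "g_use": 0.8})
    return tl.simulate(cfg, seed=42)


@pytest.fixture(scope="session")
def desk_obs(desk_sim):
    return tl.to_observations(desk_sim.matches)


@pytest.fixture(scope="session")
def desk_design(desk_sim, desk_obs):
    return tl.build_design(desk_obs, tl.WindowConfig(),
                           season_starts=desk_sim.season_starts)


@pytest.fixture(scope="session")
def small_fit(desk_design):
    """Full-model posterior on the desk league (short but converged chains)."""
    return fit(desk_design, ModelSpec.named("full"),
               McmcSettings(chains=2, warmup=300, samples=300), seed=99)


@pytest.fixture
def matches_csv(tmp_path):
    """Three hand-written matches in the raw CSV schema."""
    path = tmp_path / "matches.csv"
    path.write_text(
        "date,league,home_team,away_team,home_manager,away_manager,"
        "home_formation,away_formation,home_goals,away_goals\n"
        "2012-09-01,Premier League,Arsenal,Chelsea,Arsene Wenger,"
        "Roberto Di Matteo,4231,433,2,1\n"
        "2012-09-02,Premier League,Liverpool,Everton,Brendan Rodgers,"
        "David Moyes,433,442,1,1\n"
        "2012-09-08,Premier League,Chelsea,Arsenal,Roberto Di Matteo,"
        "Arsene Wenger,4231,4231,0,3\n")
    return path
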