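"""Shared fixtures.

The expensive coupled runs (equilibrium spin-up, full rotations, the
scenario grid) are session-scoped and computed once; unit tests stay cheap.
All runs here use maxt = 1/24 d, the package's standard analysis step.
"""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import elatosim as es
from elatosim.config import DEFAULT_GRID
from elatosim.engine import run_rotation, spin_up
from elatosim.stand import ManagementSchedule, StandParams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

MAXT = 1.0 / 24.0


@pytest.fixture(scope="session")
def base_cfg():
    return es.SimConfig(maxt=MAXT)


@pytest.fixture(scope="session")
def stand_params():
    return StandParams()


@pytest.fixture(scope="session")
def schedule():
    return ManagementSchedule()


@pytest.fixture(scope="session")
def spun_states(base_cfg, stand_params, schedule):
    """Lazily computed no-aphid equilibrium states per (dT, co2)."""
    cache = {}

    def get(dT, co2):
        key = (float(dT), float(co2))
        if key not in cache:
            state, _ = spin_up(es.ScenarioDelta(*key), base_cfg,
                               stand_p=stand_params, schedule=schedule)
            cache[key] = state
        return cache[key]

    return get


@pytest.fixture(scope="session")
def ambient_runs(base_cfg, stand_params, schedule, spun_states):
    """Ambient (dT=0, 350) rotations with and without aphids."""
    init = spun_states(0.0, 350.0)
    off = run_rotation(init, es.ScenarioDelta(0.0, 350.0), base_cfg,
                       stand_p=stand_params, schedule=schedule)
    on = run_rotation(init, es.ScenarioDelta(0.0, 350.0),
                      replace(base_cfg, aphids_on=True),
                      stand_p=stand_params, schedule=schedule)
    return {"off": off, "on": on}


@pytest.fixture(scope="session")
def scenario_grid(base_cfg, stand_params, schedule, spun_states):
    """Full default scenario grid: dT x CO2 x aphids on/off."""
    runs = {}
    for dT in DEFAULT_GRID["dT"]:
        for co2 in DEFAULT_GRID["co2"]:
            init = spun_states(dT, co2)
            sc = es.ScenarioDelta(dT, co2)
            for aphids in (False, True):
                cfg = replace(base_cfg, aphids_on=aphids)
                runs[(dT, co2, aphids)] = run_rotation(
                    init, sc, cfg, stand_p=stand_params, schedule=schedule)
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(20220217)
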