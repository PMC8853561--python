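"""Fixed-step integration of the coupled stand-aphid-climate system.

The full state (stand pools, ten aphid stages, cumulative boundary-flux
ledgers) is advanced with classical 4th-order Runge-Kutta at a fixed step
``maxt`` that divides one day.  Thinning events are represented as constant
stem-removal rates active for exactly one day (the removal rate is fixed
from the stem density at the start of the event day, so the removed total
is independent of ``maxt``).  The model is fully deterministic: identical
configurations produce bit-identical trajectories.

Scenario runs follow the protocol: spin the no-aphid stand to its 60-year
repeating equilibrium under the scenario's temperature increment and CO2
level (management included), then apply the aphid inoculum at time zero of
the reported rotation.

Cumulative boundary fluxes are integrated alongside the pools, so the mass
balance audit can verify, interval by interval, that the change of total
system C (and N) equals inputs minus outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .aphids import (
    AphidParams, aphid_derivs,
    AP_MC_ADULT, AP_MFRAC, AP_NC_BODY,
    FX_UPT_C, FX_UPT_N, FX_RESP, FX_HONEY_C, FX_EXCR_N,
    FX_CORPSE_C, FX_CORPSE_N, FX_EMIG_C, FX_EMIG_N,
    FX_IMMIG_C, FX_IMMIG_N, N_FLUX,
)
from .climate import ScenarioDelta, SeasonalDriverSpec, weather_kernel
from .stand import (
    HarvestSummary, ManagementSchedule, StandParams, StandState,
    clear_fell, planting_state, stand_derivs, SP_SLA,
)
from .state import (
    APHID_STAGE_NAMES, I_APH, I_CFOL, I_CLE, I_CLIT, I_CSOIL, I_CUM_ARESP,
    I_CUM_EMIG_C, I_CUM_EMIG_N, I_CUM_HARV_C, I_CUM_HARV_N, I_CUM_NDEP,
    I_CUM_NLEACH, I_CUM_PHOTO, I_CUM_RPLANT, I_CUM_RSOIL, I_CWOOD, I_CROOT,
    I_NLE, I_NLIT, I_NMIN, I_NSOIL, I_NSTEMS, N_APH, N_STATE,
)

__all__ = [
    "SimConfig",
    "Trajectory",
    "IntegrationError",
    "rk4_step",
    "integrate_fixed",
    "spin_up",
    "run_rotation",
    "run_scenario",
    "mass_balance_audit",
]

NEG_CLAMP = 1.0e-12     # negatives larger than this are an integration failure

WEATHER_NAMES = ("T_air", "T_soil", "RH", "PAR", "wind", "rain", "CO2")
POOL_NAMES = ("n_stems", "c_fol", "c_wood", "c_root", "c_le", "n_le",
              "c_lit", "n_lit", "c_soil", "n_soil", "n_min")
LEDGER_NAMES = ("cum_photosynthesis", "cum_plant_resp", "cum_soil_resp",
                "cum_aphid_resp", "cum_harvest_c", "cum_harvest_n",
                "cum_emigration_c", "cum_emigration_n", "cum_n_deposition",
                "cum_n_leaching")


class IntegrationError(RuntimeError):
    """Raised when the integrator produces NaN/Inf or material negativity."""

    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


@dataclass(frozen=True)
class SimConfig:
    """Integration and scenario-protocol settings.

    ``maxt`` (d) must divide one day; the default half-hour step resolves
    the diurnal temperature forcing that drives the aphid directly.  The
    output cadence is a multiple of ``maxt``.
    """

    maxt: float = 1.0 / 48.0
    rotation_years: int = 60
    output_cadence: float = 1.0        # d
    spinup_tol: float = 1.0e-4
    spinup_max_rotations: int = 50
    aphids_on: bool = False
    inoculum: float = 1.0              # apterous adults per stem at time zero

    def __post_init__(self):
        steps = 1.0 / self.maxt
        if self.maxt <= 0 or abs(steps - round(steps)) > 1e-9:
            raise ValueError("maxt must be positive and divide 1 d")
        ratio = self.output_cadence / self.maxt
        if self.output_cadence < self.maxt or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("output cadence must be a multiple of maxt")
        if self.rotation_years <= 0:
            raise ValueError("rotation length must be positive")

    @property
    def steps_per_day(self) -> int:
        return round(1.0 / self.maxt)

    @property
    def record_every(self) -> int:
        return round(self.output_cadence / self.maxt)


# --------------------------------------------------------------------------
# generic RK4 (oracle-testable surface)
# --------------------------------------------------------------------------

def rk4_step(fun, t: float, y: np.ndarray, h: float) -> np.ndarray:
    """One classical Runge-Kutta 4 step of ``dy/dt = fun(t, y)``."""
    y = np.asarray(y, dtype=float)
    k1 = np.asarray(fun(t, y))
    k2 = np.asarray(fun(t + h / 2.0, y + h / 2.0 * k1))
    k3 = np.asarray(fun(t + h / 2.0, y + h / 2.0 * k2))
    k4 = np.asarray(fun(t + h, y + h * k3))
    return y + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate_fixed(fun, t0: float, y0: np.ndarray, h: float, n_steps: int
                    ) -> np.ndarray:
    """Integrate with fixed-step RK4; returns the state after ``n_steps``."""
    y = np.asarray(y0, dtype=float)
    t = t0
    for _ in range(n_steps):
        y = rk4_step(fun, t, y, h)
        t += h
    return y


# --------------------------------------------------------------------------
# compiled coupled kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _weather_at(t, clim, dT, co2, ftab, fdt, wbuf):
    """Weather at time t: parametric synthesis, or an external forcing table.

    A non-empty ``ftab`` (rows of T_air, T_soil, RH, PAR, wind, rain, CO2 at
    uniform cadence ``fdt`` starting at t=0) is linearly interpolated and
    extended periodically; the scenario delta is applied on top either way.
    """
    n = ftab.shape[0]
    if n == 0:
        weather_kernel(t, clim, dT, co2, wbuf)
        return
    x = t / fdt
    i0 = int(math.floor(x))
    w1 = x - i0
    i0 = i0 % n
    i1 = (i0 + 1) % n
    for j in range(7):
        wbuf[j] = (1.0 - w1) * ftab[i0, j] + w1 * ftab[i1, j]
    wbuf[0] += dT
    wbuf[1] += dT
    wbuf[6] = co2


@njit(cache=True)
def _rhs(t, y, dy, clim, sp, app, dT, co2, aphids_on, thin_stem_rate,
         ftab, fdt, wbuf, fx):
    _weather_at(t, clim, dT, co2, ftab, fdt, wbuf)
    t_air = wbuf[0]
    t_soil = wbuf[1]
    par = wbuf[3]
    rain = wbuf[5]

    for i in range(N_STATE):
        dy[i] = 0.0

    n_stems = y[I_NSTEMS]
    thin_rel = 0.0
    if thin_stem_rate > 0.0 and n_stems > 0.0:
        thin_rel = thin_stem_rate / n_stems

    aph_upt_c = 0.0
    aph_upt_n = 0.0
    aph_lit_c = 0.0
    aph_lit_n = 0.0
    aph_soil_c = 0.0
    aph_soil_n = 0.0
    if aphids_on:
        c_fol = y[I_CFOL]
        lai = sp[SP_SLA] * c_fol
        if n_stems > 0.0:
            lai_per_stem = lai / n_stems
        else:
            lai_per_stem = 0.0
        if c_fol > 0.0:
            conc_c = y[I_CLE] / c_fol
            conc_n = y[I_NLE] / c_fol
        else:
            conc_c = 0.0
            conc_n = 0.0
        aphid_derivs(y[I_APH:I_APH + N_APH], t_air, lai_per_stem,
                     conc_c, conc_n, n_stems, app,
                     dy[I_APH:I_APH + N_APH], fx)
        aph_upt_c = fx[FX_UPT_C]
        aph_upt_n = fx[FX_UPT_N]
        aph_lit_c = fx[FX_HONEY_C]
        aph_lit_n = fx[FX_EXCR_N]
        # corpses, plus aphids killed on stems being thinned, go to the soil
        biomass_c = 0.0
        for j in range(5):
            biomass_c += (y[I_APH + j] + y[I_APH + 5 + j]) * app[AP_MFRAC + j]
        biomass_c *= app[AP_MC_ADULT] * n_stems
        kill_c = thin_rel * biomass_c
        aph_soil_c = fx[FX_CORPSE_C] + kill_c
        aph_soil_n = fx[FX_CORPSE_N] + kill_c * app[AP_NC_BODY]
        dy[I_CUM_ARESP] = fx[FX_RESP]
        # net migration export: emigration minus any background immigration
        dy[I_CUM_EMIG_C] = fx[FX_EMIG_C] - fx[FX_IMMIG_C]
        dy[I_CUM_EMIG_N] = fx[FX_EMIG_N] - fx[FX_IMMIG_N]

    p_gross, r_plant, r_soil, harv_c, harv_n, dep, leach = stand_derivs(
        y, dy, t_air, t_soil, par, rain, co2, sp, thin_rel,
        aph_upt_c, aph_upt_n, aph_lit_c, aph_lit_n, aph_soil_c, aph_soil_n)
    dy[I_CUM_PHOTO] = p_gross
    dy[I_CUM_RPLANT] = r_plant
    dy[I_CUM_RSOIL] = r_soil
    dy[I_CUM_HARV_C] = harv_c
    dy[I_CUM_HARV_N] = harv_n
    dy[I_CUM_NDEP] = dep
    dy[I_CUM_NLEACH] = leach


@njit(cache=True)
def _run_span(y, t0, n_days, spd, h, clim, sp, app, dT, co2, aphids_on,
              event_days, event_fracs, ftab, fdt, record_every,
              rec_t, rec_y, rec_w):
    """Integrate ``n_days`` from ``t0``; record every ``record_every`` steps.

    Returns (status, n_recorded, t_fail): status 0 = ok, 1 = material
    negativity, 2 = non-finite state.
    """
    dy = np.empty(N_STATE)
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    yt = np.empty(N_STATE)
    wbuf = np.empty(7)
    fx = np.empty(N_FLUX)

    n_rec = 0
    step_count = 0
    t = t0
    for day in range(n_days):
        thin_rate = 0.0
        for e in range(event_days.shape[0]):
            if event_days[e] == day:
                thin_rate = event_fracs[e] * y[I_NSTEMS]
        for s in range(spd):
            if step_count % record_every == 0:
                _weather_at(t, clim, dT, co2, ftab, fdt, wbuf)
                rec_t[n_rec] = t
                for i in range(N_STATE):
                    rec_y[n_rec, i] = y[i]
                for i in range(7):
                    rec_w[n_rec, i] = wbuf[i]
                n_rec += 1
            _rhs(t, y, k1, clim, sp, app, dT, co2, aphids_on, thin_rate,
                 ftab, fdt, wbuf, fx)
            for i in range(N_STATE):
                yt[i] = y[i] + 0.5 * h * k1[i]
            _rhs(t + 0.5 * h, yt, k2, clim, sp, app, dT, co2, aphids_on,
                 thin_rate, ftab, fdt, wbuf, fx)
            for i in range(N_STATE):
                yt[i] = y[i] + 0.5 * h * k2[i]
            _rhs(t + 0.5 * h, yt, k3, clim, sp, app, dT, co2, aphids_on,
                 thin_rate, ftab, fdt, wbuf, fx)
            for i in range(N_STATE):
                yt[i] = y[i] + h * k3[i]
            _rhs(t + h, yt, k4, clim, sp, app, dT, co2, aphids_on,
                 thin_rate, ftab, fdt, wbuf, fx)
            for i in range(N_STATE):
                y[i] = y[i] + h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            # guard the physical pools and stages
            for i in range(I_APH + N_APH):
                v = y[i]
                if not np.isfinite(v):
                    return 2, n_rec, t
                if v < 0.0:
                    if v > -NEG_CLAMP:
                        y[i] = 0.0
                    else:
                        return 1, n_rec, t
            t = t0 + day + (s + 1) * h
            step_count += 1
    # final record
    _weather_at(t, clim, dT, co2, ftab, fdt, wbuf)
    rec_t[n_rec] = t
    for i in range(N_STATE):
        rec_y[n_rec, i] = y[i]
    for i in range(7):
        rec_w[n_rec, i] = wbuf[i]
    n_rec += 1
    return 0, n_rec, t


# --------------------------------------------------------------------------
# trajectory container
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Recorded time series of one rotation plus its harvest summary."""

    data: pd.DataFrame
    scenario: ScenarioDelta
    config: SimConfig
    harvest: HarvestSummary | None = None
    meta: dict = field(default_factory=dict)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def rho_aph(self) -> np.ndarray:
        return self.data["rho_aph"].to_numpy()

    @property
    def final_state(self) -> StandState:
        row = self.data.iloc[-1]
        return StandState(**{
            "n_stems": row["n_stems"], "c_fol": row["c_fol"],
            "c_wood": row["c_wood"], "c_root": row["c_root"],
            "c_le": row["c_le"], "n_le": row["n_le"],
            "c_lit": row["c_lit"], "n_lit": row["n_lit"],
            "c_soil": row["c_soil"], "n_soil": row["n_soil"],
            "n_min": row["n_min"]})

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _records_to_frame(rec_t, rec_y, rec_w, n_rec, stand_p: StandParams,
                      aphid_p: AphidParams) -> pd.DataFrame:
    t = rec_t[:n_rec]
    y = rec_y[:n_rec]
    w = rec_w[:n_rec]
    cols = {"time": t}
    for i, name in enumerate(WEATHER_NAMES):
        cols[name] = w[:, i]
    for i, name in enumerate(POOL_NAMES):
        cols[name] = y[:, i]
    for i, name in enumerate(APHID_STAGE_NAMES):
        cols[name] = y[:, I_APH + i]
    cols["rho_aph"] = y[:, I_APH:I_APH + N_APH].sum(axis=1)
    cols["lai"] = stand_p.sla * y[:, I_CFOL]
    masses = aphid_p.stage_mass_c()
    aph_c = (y[:, I_APH:I_APH + N_APH] @ masses) * y[:, I_NSTEMS]
    cols["aphid_biomass_c"] = aph_c
    cols["total_c"] = (y[:, I_CFOL] + y[:, I_CWOOD] + y[:, I_CROOT]
                       + y[:, I_CLE] + y[:, I_CLIT] + y[:, I_CSOIL] + aph_c)
    cols["total_n"] = (stand_p.nu_fol * y[:, I_CFOL]
                       + stand_p.nu_wood * y[:, I_CWOOD]
                       + stand_p.nu_root * y[:, I_CROOT]
                       + y[:, I_NLE] + y[:, I_NLIT] + y[:, I_NSOIL]
                       + y[:, I_NMIN] + aph_c * aphid_p.nc_body)
    ledger_idx = (I_CUM_PHOTO, I_CUM_RPLANT, I_CUM_RSOIL, I_CUM_ARESP,
                  I_CUM_HARV_C, I_CUM_HARV_N, I_CUM_EMIG_C, I_CUM_EMIG_N,
                  I_CUM_NDEP, I_CUM_NLEACH)
    for name, idx in zip(LEDGER_NAMES, ledger_idx):
        cols[name] = y[:, idx]
    return pd.DataFrame(cols)


# --------------------------------------------------------------------------
# protocol operations
# --------------------------------------------------------------------------

def _forcing_table(forcing) -> tuple[np.ndarray, float]:
    """Validate an external forcing frame into (table, cadence) form."""
    if forcing is None:
        return np.empty((0, 7)), 1.0
    t = forcing["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("forcing time grid must be uniform")
    cols = ["T_air", "T_soil", "RH", "PAR", "wind", "rain", "CO2"]
    return np.ascontiguousarray(forcing[cols].to_numpy(dtype=float)), float(dt[0])


def _integrate(y: np.ndarray, t0: float, n_days: int, cfg: SimConfig,
               climate: SeasonalDriverSpec, stand_p: StandParams,
               aphid_p: AphidParams, scenario: ScenarioDelta,
               schedule: ManagementSchedule, aphids_on: bool,
               record: bool = True, forcing=None):
    spd = cfg.steps_per_day
    rec_every = cfg.record_every if record else n_days * spd + 1
    n_steps = n_days * spd
    n_rec_max = n_steps // rec_every + 2
    rec_t = np.empty(n_rec_max)
    rec_y = np.empty((n_rec_max, N_STATE))
    rec_w = np.empty((n_rec_max, 7))
    event_days, event_fracs = schedule.event_arrays()
    ftab, fdt = _forcing_table(forcing)
    status, n_rec, t_fail = _run_span(
        y, float(t0), n_days, spd, cfg.maxt, climate.pack(), stand_p.pack(),
        aphid_p.pack(), scenario.dT, scenario.co2, aphids_on,
        event_days, event_fracs, ftab, fdt, rec_every, rec_t, rec_y, rec_w)
    if status == 2:
        raise IntegrationError(f"non-finite state at t={t_fail:.4f} d",
                               t=t_fail, state=y.copy())
    if status == 1:
        raise IntegrationError(
            f"state driven below -{NEG_CLAMP:g} at t={t_fail:.4f} d",
            t=t_fail, state=y.copy())
    return rec_t, rec_y, rec_w, n_rec


def fell_and_replant(y: np.ndarray, schedule: ManagementSchedule,
                     stand_p: StandParams) -> np.ndarray:
    """Clear-fell the standing crop, transfer residues, and replant.

    Stem wood C (and its N) joins the harvest ledger; foliage and substrate
    pools go to surface litter, roots to soil; any aphids present die with
    the crop (biomass to soil is handled by the caller since it needs the
    aphid parameterization).  Litter, soil and mineral N carry over.
    """
    out = y.copy()
    out[I_CUM_HARV_C] += y[I_CWOOD]
    out[I_CUM_HARV_N] += stand_p.nu_wood * y[I_CWOOD]
    out[I_CLIT] += y[I_CFOL] + y[I_CLE]
    out[I_NLIT] += stand_p.nu_fol * y[I_CFOL] + y[I_NLE]
    out[I_CSOIL] += y[I_CROOT]
    out[I_NSOIL] += stand_p.nu_root * y[I_CROOT]
    out[I_NSTEMS] = schedule.planting_density
    out[I_CFOL] = schedule.planting_lai / stand_p.sla
    out[I_CWOOD] = 1.0e-4
    out[I_CROOT] = 1.0e-4
    out[I_CLE] = 3.0e-5
    out[I_NLE] = 3.0e-6
    out[I_APH:I_APH + N_APH] = 0.0
    return out


def spin_up(scenario: ScenarioDelta, cfg: SimConfig,
            climate: SeasonalDriverSpec | None = None,
            stand_p: StandParams | None = None,
            schedule: ManagementSchedule | None = None,
            initial: StandState | None = None,
            forcing=None) -> tuple[StandState, int]:
    """No-aphid spin-up to the 60-year repeating equilibrium.

    Runs full rotations (management included, aphids off) until the
    start-of-rotation state changes by less than ``cfg.spinup_tol``
    (relative, per pool) between consecutive rotations.  Returns the
    converged rotation-start state and the number of rotations used.
    """
    climate = climate or SeasonalDriverSpec()
    stand_p = stand_p or StandParams()
    schedule = schedule or ManagementSchedule()
    aphid_p = AphidParams()
    n_days = cfg.rotation_years * 365

    start = initial or planting_state(schedule, stand_p, StandState())
    y = start.to_vector()
    prev = y[:I_NMIN + 1].copy()
    for rot in range(1, cfg.spinup_max_rotations + 1):
        _integrate(y, 0.0, n_days, cfg, climate, stand_p, aphid_p,
                   scenario, schedule, aphids_on=False, record=False,
                   forcing=forcing)
        y = fell_and_replant(y, schedule, stand_p)
        cur = y[:I_NMIN + 1]
        scale = np.maximum(np.abs(prev), 1e-9)
        change = float(np.max(np.abs(cur - prev) / scale))
        if change < cfg.spinup_tol:
            return StandState.from_vector(y), rot
        prev = cur.copy()
    raise IntegrationError(
        f"spin-up did not converge within {cfg.spinup_max_rotations} "
        f"rotations (last relative change {change:.3g})")


def run_rotation(initial: StandState, scenario: ScenarioDelta, cfg: SimConfig,
                 climate: SeasonalDriverSpec | None = None,
                 stand_p: StandParams | None = None,
                 schedule: ManagementSchedule | None = None,
                 aphid_p: AphidParams | None = None,
                 forcing=None) -> Trajectory:
    """Integrate one full rotation and return the recorded trajectory.

    When ``cfg.aphids_on`` the inoculum (apterous adults per stem) is applied
    at time zero.  The harvest summary (yield class Y_C, system carbon
    C_sys) is attached; cumulative closure errors go into ``meta``.
    ``forcing`` optionally supplies an external uniform-cadence weather
    table (the schema of :func:`elatosim.climate.read_forcing_csv`),
    extended periodically over the rotation; the scenario delta still
    applies on top of it.
    """
    climate = climate or SeasonalDriverSpec()
    stand_p = stand_p or StandParams()
    schedule = schedule or ManagementSchedule()
    aphid_p = aphid_p or AphidParams()
    n_days = cfg.rotation_years * 365

    y = initial.to_vector()
    # zero the ledgers: the trajectory accounts for this rotation only
    y[I_CUM_PHOTO:] = 0.0
    if cfg.aphids_on:
        y[I_APH + 4] = cfg.inoculum
    rec_t, rec_y, rec_w, n_rec = _integrate(
        y, 0.0, n_days, cfg, climate, stand_p, aphid_p, scenario, schedule,
        aphids_on=cfg.aphids_on, forcing=forcing)
    data = _records_to_frame(rec_t, rec_y, rec_w, n_rec, stand_p, aphid_p)

    final = StandState.from_vector(y)
    events = _harvest_events(data, schedule, stand_p)
    harvest = clear_fell(final, cfg.rotation_years, y[I_CUM_HARV_C],
                         stand_p, events)
    traj = Trajectory(data=data, scenario=scenario, config=cfg, harvest=harvest)
    c_err, n_err = mass_balance_audit(traj)
    traj.meta.update({
        "closure_c": c_err, "closure_n": n_err,
        "aphids_on": cfg.aphids_on, "maxt": cfg.maxt,
        "peak_rho_aph": float(data["rho_aph"].max()),
    })
    return traj


def _harvest_events(data: pd.DataFrame, schedule: ManagementSchedule,
                    stand_p: StandParams) -> list:
    events = []
    t = data["time"].to_numpy()
    cum = data["cum_harvest_c"].to_numpy()
    stems = data["n_stems"].to_numpy()
    for year, frac in schedule.thinnings:
        day = year * 365
        i0 = int(np.searchsorted(t, day))
        i1 = int(np.searchsorted(t, day + schedule.event_duration))
        if i1 >= len(t):
            continue
        events.append((float(day),
                       float(stems[i0] - stems[min(i1, len(t) - 1)]),
                       float((cum[i1] - cum[i0]) / stand_p.c_per_volume * 1e4)))
    return events


def run_scenario(scenario: ScenarioDelta, cfg: SimConfig,
                 climate: SeasonalDriverSpec | None = None,
                 stand_p: StandParams | None = None,
                 schedule: ManagementSchedule | None = None,
                 aphid_p: AphidParams | None = None,
                 spun_up: StandState | None = None) -> Trajectory:
    """Spin up (aphids off) and run the reported rotation for one scenario."""
    if spun_up is None:
        spun_up, _ = spin_up(scenario, replace(cfg, aphids_on=False),
                             climate, stand_p, schedule)
    return run_rotation(spun_up, scenario, cfg, climate, stand_p, schedule,
                        aphid_p)


def mass_balance_audit(tr: Trajectory) -> tuple[float, float]:
    """Maximum relative C and N closure errors over all output intervals.

    For each interval between consecutive records the change in total system
    C (N) is compared with the integrated boundary fluxes; errors are
    normalized by the running maximum of the total.
    """
    d = tr.data
    tot_c = d["total_c"].to_numpy()
    tot_n = d["total_n"].to_numpy()
    c_in = d["cum_photosynthesis"].to_numpy()
    c_out = (d["cum_plant_resp"] + d["cum_soil_resp"] + d["cum_aphid_resp"]
             + d["cum_harvest_c"] + d["cum_emigration_c"]).to_numpy()
    n_in = d["cum_n_deposition"].to_numpy()
    n_out = (d["cum_n_leaching"] + d["cum_harvest_n"]
             + d["cum_emigration_n"]).to_numpy()
    c_err = np.abs(np.diff(tot_c) - np.diff(c_in - c_out)) / np.max(tot_c)
    n_err = np.abs(np.diff(tot_n) - np.diff(n_in - n_out)) / np.max(tot_n)
    return float(c_err.max()), float(n_err.max())
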