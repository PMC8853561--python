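"""Reduced-form carbon/nitrogen Sitka-spruce stand model.

This is a compact stand surrogate in the substrate (transport-resistance)
modelling tradition: gross canopy photosynthesis feeds a
foliage-associated substrate C pool (``C_le``), root uptake of mineral N
feeds a substrate N pool (``N_le``), and structural growth of foliage, wood
and fine roots draws on both substrates with saturating kinetics.  Litter
and soil-organic pools close the C and N cycles; stem wood leaves the system
only through harvest.  The surrogate exposes exactly the interfaces the
aphid herbivore needs — leaf area index, phloem substrate concentrations,
stem density, and litter/soil return pathways — and conserves C and N to
machine precision at the derivative level.

Plantation management follows the standard upland regime: planting at
0.25 stems m-2 and leaf area index 0.003, thinnings removing fractions
0.45, 0.40, 0.35, 0.30, 0.25, 0.20, 0.15, 0.10 of the standing stems at
years 20, 25, ..., 55 (each spread at constant rate over one day, nominally
1 January), and clear-felling at 60 years.  Harvested stem-wood C is
converted to merchantable volume with a fixed wood basic density and C
fraction; the yield class Y_C is the harvested volume per hectare averaged
over the rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .climate import WeatherInstant
from .state import (
    I_NSTEMS, I_CFOL, I_CWOOD, I_CROOT, I_CLE, I_NLE,
    I_CLIT, I_NLIT, I_CSOIL, I_NSOIL, I_NMIN, N_STATE,
)

__all__ = [
    "StandParams",
    "StandState",
    "ManagementSchedule",
    "HarvestSummary",
    "canopy_photosynthesis",
    "growth_allocation_step",
    "aphid_drain",
    "thinning_event",
    "clear_fell",
]


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StandParams:
    """Stand surrogate parameters (SI with days; C/N in kg m-2).

    The values below were set once from typical Sitka-spruce physiology and
    upland-Britain soils so that a no-aphid ambient rotation closes its
    canopy within the first two decades and yields a stem-wood volume inside
    the conventional 9-15 m3 ha-1 y-1 yield-class corridor.
    """

    # canopy & photosynthesis
    sla: float = 12.0             # specific leaf area, m2 leaf (kg C foliage)-1
    k_ext: float = 0.5            # canopy extinction coefficient
    alpha: float = 2.5e-9         # leaf quantum yield, kg C (J PAR)-1
    pmax: float = 0.024           # leaf light-saturated rate, kg C m-2 leaf d-1
    k_co2: float = 300.0          # Michaelis constant of Pmax on CO2, umol mol-1
    t_min_ph: float = -5.0        # photosynthesis temperature response (°C)
    t_opt_ph: float = 18.0
    t_max_ph: float = 36.0
    sig_c_inh: float = 0.06       # product inhibition scale on sigma_C
    # growth & allocation (relative to foliage structural C)
    g_fol: float = 0.006          # d-1
    g_wood: float = 0.0032        # d-1
    g_root: float = 0.003         # d-1
    k_sig_c: float = 0.05         # half-saturation of growth on sigma_C
    k_sig_n: float = 0.005        # half-saturation of growth on sigma_N
    q10_growth: float = 2.0
    t_ref: float = 10.0           # °C reference for Q10 responses
    lai_max: float = 8.0          # self-shading cap on foliage expansion
    r_growth: float = 0.25        # growth respiration per unit structural C
    # turnover (d-1) and tissue stoichiometry (kg N per kg C)
    s_fol: float = 5.0e-4         # needle lifespan ~5.5 y
    s_wood: float = 1.0e-5
    s_root: float = 2.5e-3        # fine-root lifespan ~1 y
    nu_fol: float = 0.025
    nu_wood: float = 0.003
    nu_root: float = 0.015
    # maintenance respiration (d-1 on structural C)
    m_fol: float = 8.0e-4
    m_wood: float = 4.0e-5
    m_root: float = 1.2e-3
    q10_resp: float = 2.0
    k_sig_maint: float = 0.002    # substrate throttle on maintenance
    # mineral-N cycle
    u_nmax: float = 0.03          # d-1 on root C, max specific N uptake
    k_nmin: float = 0.002         # kg N m-2 half-saturation
    sig_n_inh: float = 0.02       # N-uptake inhibition on N_le/C_fol
    n_dep: float = 6.0e-6         # kg N m-2 d-1 atmospheric deposition
    k_leach: float = 5.0e-3       # d-1 on mineral N at reference rain
    rain_ref: float = 4.225       # mm d-1
    k_nle_turn: float = 1.0e-3    # d-1, substrate-N recycling to mineral N
    # decomposition
    k_lit: float = 2.0e-3         # d-1 at t_ref
    f_hum: float = 0.3            # humified fraction of litter decay
    k_soil: float = 1.2e-4        # d-1 at t_ref
    q10_soil: float = 2.0
    # harvest conversion
    wood_density: float = 400.0   # kg DM m-3
    c_fraction: float = 0.5       # kg C (kg DM)-1

    def pack(self) -> np.ndarray:
        return np.array([
            self.sla, self.k_ext, self.alpha, self.pmax, self.k_co2,
            self.t_min_ph, self.t_opt_ph, self.t_max_ph, self.sig_c_inh,
            self.g_fol, self.g_wood, self.g_root, self.k_sig_c, self.k_sig_n,
            self.q10_growth, self.t_ref, self.lai_max, self.r_growth,
            self.s_fol, self.s_wood, self.s_root,
            self.nu_fol, self.nu_wood, self.nu_root,
            self.m_fol, self.m_wood, self.m_root, self.q10_resp, self.k_sig_maint,
            self.u_nmax, self.k_nmin, self.sig_n_inh, self.n_dep, self.k_leach,
            self.rain_ref, self.k_nle_turn, self.k_lit, self.f_hum,
            self.k_soil, self.q10_soil, self.wood_density, self.c_fraction,
        ], dtype=np.float64)

    @property
    def c_per_volume(self) -> float:
        """kg stem C per m3 of merchantable timber."""
        return self.wood_density * self.c_fraction


# packed indices (keep in sync with StandParams.pack)
(SP_SLA, SP_KEXT, SP_ALPHA, SP_PMAX, SP_KCO2,
 SP_TMIN, SP_TOPT, SP_TMAX, SP_SIGC_INH,
 SP_GFOL, SP_GWOOD, SP_GROOT, SP_KSIGC, SP_KSIGN,
 SP_Q10G, SP_TREF, SP_LAIMAX, SP_RG,
 SP_SFOL, SP_SWOOD, SP_SROOT,
 SP_NUFOL, SP_NUWOOD, SP_NUROOT,
 SP_MFOL, SP_MWOOD, SP_MROOT, SP_Q10R, SP_KSIGM,
 SP_UNMAX, SP_KNMIN, SP_SIGN_INH, SP_NDEP, SP_KLEACH,
 SP_RAINREF, SP_KNLETURN, SP_KLIT, SP_FHUM, SP_KSOIL, SP_Q10S,
 SP_WOODDENS, SP_CFRAC) = range(42)


# --------------------------------------------------------------------------
# state containers
# --------------------------------------------------------------------------

@dataclass
class StandState:
    """Per-ground-area tree, litter and soil pools (kg m-2; stems m-2)."""

    n_stems: float = 0.25
    c_fol: float = 2.5e-4
    c_wood: float = 1.0e-4
    c_root: float = 1.0e-4
    c_le: float = 3.0e-5
    n_le: float = 3.0e-6
    c_lit: float = 1.5
    n_lit: float = 0.045
    c_soil: float = 12.0
    n_soil: float = 0.60
    n_min: float = 0.005

    def lai(self, p: StandParams) -> float:
        return p.sla * self.c_fol

    def to_vector(self, y: np.ndarray | None = None) -> np.ndarray:
        if y is None:
            y = np.zeros(N_STATE)
        y[I_NSTEMS] = self.n_stems
        y[I_CFOL] = self.c_fol
        y[I_CWOOD] = self.c_wood
        y[I_CROOT] = self.c_root
        y[I_CLE] = self.c_le
        y[I_NLE] = self.n_le
        y[I_CLIT] = self.c_lit
        y[I_NLIT] = self.n_lit
        y[I_CSOIL] = self.c_soil
        y[I_NSOIL] = self.n_soil
        y[I_NMIN] = self.n_min
        return y

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "StandState":
        return cls(n_stems=y[I_NSTEMS], c_fol=y[I_CFOL], c_wood=y[I_CWOOD],
                   c_root=y[I_CROOT], c_le=y[I_CLE], n_le=y[I_NLE],
                   c_lit=y[I_CLIT], n_lit=y[I_NLIT], c_soil=y[I_CSOIL],
                   n_soil=y[I_NSOIL], n_min=y[I_NMIN])

    def total_c(self) -> float:
        return (self.c_fol + self.c_wood + self.c_root + self.c_le
                + self.c_lit + self.c_soil)

    def total_n(self, p: StandParams) -> float:
        return (p.nu_fol * self.c_fol + p.nu_wood * self.c_wood
                + p.nu_root * self.c_root + self.n_le + self.n_lit
                + self.n_soil + self.n_min)


def planting_state(schedule: "ManagementSchedule", p: StandParams,
                   carryover: StandState | None = None) -> StandState:
    """Stand state at planting; litter/soil pools carry over between rotations."""
    s = StandState(
        n_stems=schedule.planting_density,
        c_fol=schedule.planting_lai / p.sla,
        c_wood=1.0e-4, c_root=1.0e-4, c_le=3.0e-5, n_le=3.0e-6,
    )
    if carryover is not None:
        s.c_lit, s.n_lit = carryover.c_lit, carryover.n_lit
        s.c_soil, s.n_soil = carryover.c_soil, carryover.n_soil
        s.n_min = carryover.n_min
    return s


@dataclass(frozen=True)
class ManagementSchedule:
    """Planting, thinning and clear-fell plan for one rotation.

    ``thinnings`` maps rotation year -> fraction of standing stems removed;
    events run at constant rate for ``event_duration`` days starting on
    1 January of the scheduled year.
    """

    planting_density: float = 0.25    # stems m-2
    planting_lai: float = 0.003
    thinnings: tuple = ((20, 0.45), (25, 0.40), (30, 0.35), (35, 0.30),
                        (40, 0.25), (45, 0.20), (50, 0.15), (55, 0.10))
    clearfell_year: int = 60
    event_duration: float = 1.0       # d

    def __post_init__(self):
        years = [y for y, _ in self.thinnings]
        if years != sorted(years) or len(set(years)) != len(years):
            raise ValueError("thinning years must be strictly increasing")
        for y, f in self.thinnings:
            if not 0.0 < f < 1.0:
                raise ValueError(f"thinning fraction out of (0,1): {f}")
            if y >= self.clearfell_year:
                raise ValueError("thinning scheduled at or after clear-fell")
        if self.planting_density <= 0 or self.planting_lai <= 0:
            raise ValueError("planting density and LAI must be positive")

    @property
    def rotation_years(self) -> int:
        return self.clearfell_year

    def event_arrays(self):
        """(day-of-rotation indices, fractions) for the thinning events."""
        days = np.array([int(y * 365) for y, _ in self.thinnings], dtype=np.int64)
        fracs = np.array([f for _, f in self.thinnings], dtype=np.float64)
        return days, fracs


@dataclass
class HarvestSummary:
    """Rotation-level harvest accounting."""

    y_c: float                    # yield class, m3 ha-1 y-1
    c_sys: float                  # total system C at rotation end, kg C m-2
    total_volume: float           # m3 ha-1 over the rotation
    events: list = field(default_factory=list)  # (time d, stems removed m-2, m3 ha-1)


# --------------------------------------------------------------------------
# process kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _temp_beta(t, tmn, topt, tmx):
    if t <= tmn or t >= tmx:
        return 0.0
    return ((t - tmn) * (tmx - t)) / ((topt - tmn) * (tmx - topt))


@njit(cache=True)
def canopy_photo_kernel(par, t_air, co2, lai, sp):
    """Big-leaf gross photosynthesis, kg C m-2 ground d-1.

    Non-rectangular-in-spirit closure: rectangular hyperbola per leaf layer
    integrated over a Beer's-law light profile, with a saturating CO2 factor
    (normalized to 350 umol mol-1) and a parabolic temperature response.
    """
    if par <= 0.0 or lai <= 0.0:
        return 0.0
    f_t = _temp_beta(t_air, sp[SP_TMIN], sp[SP_TOPT], sp[SP_TMAX])
    if f_t <= 0.0:
        return 0.0
    f_c = (co2 / (co2 + sp[SP_KCO2])) / (350.0 / (350.0 + sp[SP_KCO2]))
    pmax = sp[SP_PMAX] * f_t * f_c
    k = sp[SP_KEXT]
    aki = sp[SP_ALPHA] * k * par
    return (pmax / k) * math.log((aki + pmax) /
                                 (aki * math.exp(-k * lai) + pmax))


@njit(cache=True)
def stand_derivs(y, dy, t_air, t_soil, par, rain, co2, sp, thin_rel,
                 aph_upt_c, aph_upt_n, aph_lit_c, aph_lit_n,
                 aph_soil_c, aph_soil_n):
    """Add the stand's contribution to the derivative vector ``dy``.

    ``thin_rel`` is the relative stem-removal rate (d-1) of an active
    management event; the aphid arguments are per-ground-area fluxes already
    aggregated by the caller (all zero when the aphid sub-model is off).

    Returns (gross photosynthesis, plant respiration, soil respiration,
    harvested wood C rate, harvested wood N rate, N deposition, N leaching)
    for the boundary-flux ledgers.
    """
    c_fol = y[I_CFOL]
    c_wood = y[I_CWOOD]
    c_root = y[I_CROOT]
    c_le = y[I_CLE]
    n_le = y[I_NLE]

    lai = sp[SP_SLA] * c_fol
    w_struct = c_fol + c_wood + c_root
    if w_struct > 0.0:
        sig_c = c_le / w_struct
        sig_n = n_le / w_struct
    else:
        sig_c = 0.0
        sig_n = 0.0

    # photosynthesis with end-product inhibition
    p_gross = canopy_photo_kernel(par, t_air, co2, lai, sp)
    p_gross = p_gross / (1.0 + sig_c / sp[SP_SIGC_INH])

    # substrate-driven structural growth
    f_sub = (sig_c / (sig_c + sp[SP_KSIGC])) * (sig_n / (sig_n + sp[SP_KSIGN]))
    f_tg = sp[SP_Q10G] ** ((t_air - sp[SP_TREF]) / 10.0)
    lai_room = 1.0 - lai / sp[SP_LAIMAX]
    if lai_room < 0.0:
        lai_room = 0.0
    g_fol = sp[SP_GFOL] * c_fol * f_sub * f_tg * lai_room
    g_wood = sp[SP_GWOOD] * c_fol * f_sub * f_tg
    g_root = sp[SP_GROOT] * c_fol * f_sub * f_tg
    g_tot = g_fol + g_wood + g_root

    # maintenance respiration, throttled as substrate C empties
    f_tm = sp[SP_Q10R] ** ((t_air - sp[SP_TREF]) / 10.0)
    maint = (sp[SP_MFOL] * c_fol + sp[SP_MWOOD] * c_wood
             + sp[SP_MROOT] * c_root) * f_tm
    maint *= sig_c / (sig_c + sp[SP_KSIGM])
    r_plant = sp[SP_RG] * g_tot + maint

    # turnover
    sen_f = sp[SP_SFOL] * c_fol
    sen_w = sp[SP_SWOOD] * c_wood
    sen_r = sp[SP_SROOT] * c_root

    # mineral-N uptake with end-product inhibition on the foliage-normalized
    # substrate concentration (the same signal the phloem feeder sees)
    n_min = y[I_NMIN]
    conc_n_fol = n_le / c_fol if c_fol > 0.0 else 0.0
    upt_n = (sp[SP_UNMAX] * c_root * (n_min / (n_min + sp[SP_KNMIN]))
             / (1.0 + conc_n_fol / sp[SP_SIGN_INH]))

    # decomposition (soil temperature driven)
    f_ts = sp[SP_Q10S] ** ((t_soil - sp[SP_TREF]) / 10.0)
    d_lit_c = sp[SP_KLIT] * f_ts * y[I_CLIT]
    d_lit_n = sp[SP_KLIT] * f_ts * y[I_NLIT]
    d_soil_c = sp[SP_KSOIL] * f_ts * y[I_CSOIL]
    d_soil_n = sp[SP_KSOIL] * f_ts * y[I_NSOIL]
    f_hum = sp[SP_FHUM]
    r_soil = (1.0 - f_hum) * d_lit_c + d_soil_c

    # leaching scaled by rain, plus fixed deposition; substrate-N recycling
    leach = sp[SP_KLEACH] * n_min * (rain / sp[SP_RAINREF])
    dep = sp[SP_NDEP]
    nle_turn = sp[SP_KNLETURN] * n_le

    # thinning transfers (constant-rate event; wood leaves as harvest)
    harv_c = thin_rel * c_wood
    harv_n = thin_rel * sp[SP_NUWOOD] * c_wood

    dy[I_NSTEMS] += -thin_rel * y[I_NSTEMS]
    dy[I_CFOL] += g_fol - sen_f - thin_rel * c_fol
    dy[I_CWOOD] += g_wood - sen_w - thin_rel * c_wood
    dy[I_CROOT] += g_root - sen_r - thin_rel * c_root
    dy[I_CLE] += (p_gross - (1.0 + sp[SP_RG]) * g_tot - maint
                  - aph_upt_c - thin_rel * c_le)
    dy[I_NLE] += (upt_n
                  - (sp[SP_NUFOL] * g_fol + sp[SP_NUWOOD] * g_wood
                     + sp[SP_NUROOT] * g_root)
                  - nle_turn - aph_upt_n - thin_rel * n_le)
    dy[I_CLIT] += (sen_f + sen_w + aph_lit_c
                   + thin_rel * (c_fol + c_le) - d_lit_c)
    dy[I_NLIT] += (sp[SP_NUFOL] * sen_f + sp[SP_NUWOOD] * sen_w + aph_lit_n
                   + thin_rel * (sp[SP_NUFOL] * c_fol + n_le) - d_lit_n)
    dy[I_CSOIL] += (f_hum * d_lit_c + sen_r + aph_soil_c
                    + thin_rel * c_root - d_soil_c)
    dy[I_NSOIL] += (f_hum * d_lit_n + sp[SP_NUROOT] * sen_r + aph_soil_n
                    + thin_rel * sp[SP_NUROOT] * c_root - d_soil_n)
    dy[I_NMIN] += ((1.0 - f_hum) * d_lit_n + d_soil_n + nle_turn
                   - upt_n - leach + dep)

    return p_gross, r_plant, r_soil, harv_c, harv_n, dep, leach


# --------------------------------------------------------------------------
# operations (library surface)
# --------------------------------------------------------------------------

def canopy_photosynthesis(w: WeatherInstant, lai: float,
                          p: StandParams | None = None) -> float:
    """Gross canopy C fixation (kg C m-2 ground d-1) before product inhibition."""
    if lai < 0:
        raise ValueError("LAI must be non-negative")
    sp = (p or StandParams()).pack()
    return canopy_photo_kernel(w.par, w.T_air, w.co2, float(lai), sp)


def growth_allocation_step(s: StandState, w: WeatherInstant,
                           p: StandParams | None = None) -> dict:
    """Instantaneous stand fluxes (kg C or N m-2 d-1) at state ``s``.

    Returns the named process rates; the same kernel drives the integrator,
    so these are exactly the derivatives' building blocks.
    """
    p = p or StandParams()
    sp = p.pack()
    y = s.to_vector()
    dy = np.zeros(N_STATE)
    p_gross, r_plant, r_soil, harv_c, harv_n, dep, leach = stand_derivs(
        y, dy, w.T_air, w.T_soil, w.par, w.rain, w.co2, sp,
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    conc_n_fol = s.n_le / s.c_fol if s.c_fol > 0 else 0.0
    n_uptake = (p.u_nmax * s.c_root * (s.n_min / (s.n_min + p.k_nmin))
                / (1.0 + conc_n_fol / p.sig_n_inh))
    return {
        "photosynthesis": p_gross,
        "plant_respiration": r_plant,
        "soil_respiration": r_soil,
        "growth_fol": dy[I_CFOL] + p.s_fol * s.c_fol,
        "growth_wood": dy[I_CWOOD] + p.s_wood * s.c_wood,
        "growth_root": dy[I_CROOT] + p.s_root * s.c_root,
        "senescence_fol": p.s_fol * s.c_fol,
        "senescence_wood": p.s_wood * s.c_wood,
        "senescence_root": p.s_root * s.c_root,
        "n_uptake": n_uptake,
        "n_deposition": dep,
        "n_leaching": leach,
        "dy": dy,
    }


def aphid_drain(s: StandState, uptake_c: float, uptake_n: float,
                dt: float = 1.0) -> tuple[StandState, float, float]:
    """Withdraw phloem C and N from the substrate pools over ``dt`` days.

    If a requested withdrawal exceeds the available substrate the uptake is
    rescaled to what the pool holds and the realized amounts are returned so
    the herbivore can mount its starvation response.
    """
    if uptake_c < 0 or uptake_n < 0:
        raise ValueError("uptake must be non-negative")
    want_c = uptake_c * dt
    want_n = uptake_n * dt
    real_c = min(want_c, s.c_le)
    real_n = min(want_n, s.n_le)
    out = StandState(**{k: getattr(s, k) for k in s.__dataclass_fields__})
    out.c_le -= real_c
    out.n_le -= real_n
    return out, real_c / dt, real_n / dt


def thinning_event(s: StandState, fraction: float, maxt: float = 1.0 / 48.0,
                   p: StandParams | None = None) -> tuple[float, StandState, dict]:
    """Remove ``fraction`` of standing stems at constant rate over one day.

    Returns the constant removal rate O_nstems (stems m-2 d-1, resolved to
    the integration step ``maxt``), the post-event state, and the transfer
    ledger.  Removed stems carry their proportional share of every per-stem
    pool: stem wood C (and its N) to the harvest ledger, foliage and
    substrate shares to surface litter, roots to soil.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("thinning fraction must lie in (0, 1)")
    if maxt <= 0 or (1.0 / maxt) != round(1.0 / maxt):
        raise ValueError("maxt must divide 1 d")
    rate = fraction * s.n_stems  # stems m-2 d-1 over exactly 1 d
    keep = 1.0 - fraction
    out = StandState(**{k: getattr(s, k) for k in s.__dataclass_fields__})
    p = p or StandParams()
    transfers = {
        "harvest_c": fraction * s.c_wood,
        "harvest_n": fraction * p.nu_wood * s.c_wood,
        "litter_c": fraction * (s.c_fol + s.c_le),
        "litter_n": fraction * (p.nu_fol * s.c_fol + s.n_le),
        "soil_c": fraction * s.c_root,
        "soil_n": fraction * p.nu_root * s.c_root,
        "stems_removed": fraction * s.n_stems,
    }
    out.n_stems *= keep
    out.c_fol *= keep
    out.c_wood *= keep
    out.c_root *= keep
    out.c_le *= keep
    out.n_le *= keep
    out.c_lit += transfers["litter_c"]
    out.n_lit += transfers["litter_n"]
    out.c_soil += transfers["soil_c"]
    out.n_soil += transfers["soil_n"]
    return rate, out, transfers


def clear_fell(s: StandState, rotation_years: float,
               cum_harvest_wood_c: float, p: StandParams | None = None,
               events: list | None = None) -> HarvestSummary:
    """Fell the standing crop and close the rotation's harvest accounts.

    ``cum_harvest_wood_c`` is the stem-wood C already removed by thinnings
    (kg C m-2); the standing stem wood joins it.  C_sys is the total system
    C at rotation end, standing crop included.
    """
    p = p or StandParams()
    total_wood_c = cum_harvest_wood_c + s.c_wood
    volume_ha = total_wood_c / p.c_per_volume * 1.0e4   # m3 ha-1
    y_c = volume_ha / rotation_years if rotation_years > 0 else 0.0
    return HarvestSummary(y_c=y_c, c_sys=s.total_c(),
                          total_volume=volume_ha, events=list(events or []))
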