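"""Stage-structured green spruce aphid (*Elatobium abietinum*) sub-model.

Ten state variables, all in aphids per stem: four nymphal instars plus the
adult for each of the wingless (apterous) and winged (alate) morphs.  Air
temperature is the only environmental driver that acts on the aphid
directly; the host tree enters through three signals — leaf area per stem,
and the phloem substrate concentrations of C and N (substrate pool divided
by foliage structural C).

Process structure:

* development — degree-day kinetics per instar: zero at or below the base
  temperature, linear in ``T - T_base`` up to an optimum, declining to zero
  at a ceiling;
* feeding — per-capita sap intake proportional to body C, saturating in
  phloem C concentration and divided down by crowding (aphids per m2 leaf);
  the N:C ratio of the intake is fixed by the phloem's own stoichiometry;
* reproduction — apterous adults produce nymphs at a rate saturating in
  their realized N intake with a unimodal temperature response; births are
  split between morphs by a crowding/food-quality induction rule; alate
  adults feed but do not reproduce locally and emigrate at a constant rate;
* mortality — stage-specific baseline, a cold term quadratic in the deficit
  below a threshold temperature (the overwintering bottleneck for this
  species), and a starvation term that grows as realized intake falls;
* stoichiometric closure — every kg of C and N entering an aphid is routed:
  respiration to the atmosphere, honeydew (the unassimilated sugar surplus)
  to surface litter, body growth into aphid biomass (fixed per-stage body
  masses), corpses to the soil, emigration out of the system.  When intake
  cannot cover the C or N cost of development and reproduction, those
  demographic fluxes are scaled down by the shortfall — the model's
  starvation response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .climate import WeatherInstant
from .state import APHID_STAGE_NAMES, N_APH

__all__ = [
    "AphidParams",
    "AphidState",
    "AphidFluxBundle",
    "development_rate",
    "per_capita_intake",
    "fecundity",
    "alate_fraction",
    "mortality_rate",
    "aphid_odes",
    "inoculate",
    "management_kill",
]


@dataclass(frozen=True)
class AphidParams:
    """Green spruce aphid rate parameters.

    Defaults follow generic aphid (Dixon-style) biology adapted to a
    cool-climate conifer aphid: a low developmental base temperature, about
    110 degree-days from birth to adult, sap throughput of many times body C
    per day with the large unassimilated surplus excreted as honeydew, and
    winter cold as the main mortality agent.  Every value is overridable
    through the configuration file.
    """

    # development (degree-day model)
    t_base: float = 3.0                 # °C, development threshold
    thermal_k: tuple = (28.0, 26.0, 26.0, 30.0)   # degree-days per instar
    t_opt_dev: float = 20.0             # °C, development optimum
    t_ceil_dev: float = 32.0            # °C, development ceiling
    # feeding
    intake_rel: float = 40.0            # d-1: max C intake per unit body C
    k_conc_c: float = 0.02              # half-saturation on phloem C conc.
    crowd_half: float = 600.0           # aphids m-2 leaf halving intake
    # C routing
    f_resp: float = 0.30                # respired fraction of C intake
    # reproduction (apterous adults only)
    fec_max: float = 4.0                # nymphs adult-1 d-1
    k_fec_n: float = 1.0e-8             # kg N aphid-1 d-1 half-saturation
    t_min_fec: float = 4.0              # °C
    t_opt_fec: float = 16.0
    t_max_fec: float = 30.0
    # morph determination
    alate_half: float = 400.0           # crowding at 50% alate induction
    alate_food_boost: float = 0.3       # extra induction under food stress
    emig_rate: float = 0.3              # d-1, alate adult emigration
    immigration: float = 0.0            # nymphs stem-1 d-1 deposited by
                                        # transient alates (off by default)
    # mortality
    mort_base: tuple = (0.03, 0.03, 0.03, 0.03, 0.05,
                        0.03, 0.03, 0.03, 0.03, 0.08)   # d-1 per stage
    t_cold: float = 2.0                 # °C, cold-mortality threshold
    c_cold: float = 0.055               # d-1 °C-2
    m_starv: float = 0.5                # d-1 at complete starvation
    starv_thresh: float = 0.5           # intake ratio below which starvation bites
    # body composition
    mc_adult: float = 1.0e-8            # kg C per adult aphid
    mass_frac: tuple = (0.15, 0.30, 0.50, 0.75, 1.0)    # instars 1-4, adult
    nc_body: float = 0.15               # kg N per kg body C

    def __post_init__(self):
        if len(self.thermal_k) != 4 or len(self.mass_frac) != 5:
            raise ValueError("thermal_k needs 4 entries, mass_frac needs 5")
        if len(self.mort_base) != N_APH:
            raise ValueError("mort_base needs 10 entries")
        if not 0.0 <= self.f_resp <= 1.0:
            raise ValueError("f_resp must lie in [0, 1]")
        if any(v < 0 for v in (self.intake_rel, self.fec_max, self.emig_rate,
                               self.c_cold, self.m_starv)):
            raise ValueError("rates must be non-negative")

    def stage_mass_c(self) -> np.ndarray:
        """Body C mass (kg) for the ten stages."""
        f = np.array(self.mass_frac)
        return np.concatenate([f, f]) * self.mc_adult

    def pack(self) -> np.ndarray:
        a = np.empty(N_APHP, dtype=np.float64)
        a[AP_TBASE] = self.t_base
        a[AP_TOPT_DEV] = self.t_opt_dev
        a[AP_TCEIL] = self.t_ceil_dev
        a[AP_K1:AP_K1 + 4] = self.thermal_k
        a[AP_INTAKE_REL] = self.intake_rel
        a[AP_KCONC] = self.k_conc_c
        a[AP_CROWD_HALF] = self.crowd_half
        a[AP_FRESP] = self.f_resp
        a[AP_FECMAX] = self.fec_max
        a[AP_KFECN] = self.k_fec_n
        a[AP_TMINF] = self.t_min_fec
        a[AP_TOPTF] = self.t_opt_fec
        a[AP_TMAXF] = self.t_max_fec
        a[AP_ALATE_HALF] = self.alate_half
        a[AP_ALATE_BOOST] = self.alate_food_boost
        a[AP_EMIG] = self.emig_rate
        a[AP_IMMIG] = self.immigration
        a[AP_TCOLD] = self.t_cold
        a[AP_CCOLD] = self.c_cold
        a[AP_MSTARV] = self.m_starv
        a[AP_STARV_THRESH] = self.starv_thresh
        a[AP_MC_ADULT] = self.mc_adult
        a[AP_NC_BODY] = self.nc_body
        a[AP_MORT0:AP_MORT0 + N_APH] = self.mort_base
        a[AP_MFRAC:AP_MFRAC + 5] = self.mass_frac
        return a


# packed layout
(AP_TBASE, AP_TOPT_DEV, AP_TCEIL, AP_K1, _, _, _,
 AP_INTAKE_REL, AP_KCONC, AP_CROWD_HALF, AP_FRESP,
 AP_FECMAX, AP_KFECN, AP_TMINF, AP_TOPTF, AP_TMAXF,
 AP_ALATE_HALF, AP_ALATE_BOOST, AP_EMIG,
 AP_TCOLD, AP_CCOLD, AP_MSTARV, AP_STARV_THRESH,
 AP_MC_ADULT, AP_NC_BODY) = range(25)
AP_MORT0 = 25
AP_MFRAC = 35
AP_IMMIG = 40
N_APHP = 41

# flux-slot layout for the kernel's output buffer (all kg m-2 ground d-1)
(FX_UPT_C, FX_UPT_N, FX_RESP, FX_HONEY_C, FX_EXCR_N,
 FX_CORPSE_C, FX_CORPSE_N, FX_EMIG_C, FX_EMIG_N,
 FX_GROWTH_C, FX_GROWTH_N, FX_IMMIG_C, FX_IMMIG_N) = range(13)
N_FLUX = 13


@dataclass
class AphidState:
    """Ten per-stem stage abundances."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(N_APH))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_APH,):
            raise ValueError("aphid state needs 10 stage abundances")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("stage abundances must be finite and non-negative")

    @property
    def total(self) -> float:
        """rho_aph: total aphids per stem."""
        return float(self.counts.sum())

    def biomass_c(self, p: AphidParams) -> float:
        """kg C per stem."""
        return float(self.counts @ p.stage_mass_c())

    def biomass_n(self, p: AphidParams) -> float:
        return self.biomass_c(p) * p.nc_body

    def as_dict(self) -> dict:
        return dict(zip(APHID_STAGE_NAMES, self.counts))


@dataclass(frozen=True)
class AphidFluxBundle:
    """Per-ground-area C/N fluxes routed by the aphid population (kg m-2 d-1).

    Conservation: ``uptake_c = respiration_c + honeydew_c + growth_c`` and
    ``uptake_n = excreted_n + growth_n`` hold identically; growth is the C/N
    incorporated into aphid biomass by development and reproduction.
    """

    uptake_c: float = 0.0
    uptake_n: float = 0.0
    respiration_c: float = 0.0
    honeydew_c: float = 0.0
    excreted_n: float = 0.0
    corpse_c: float = 0.0
    corpse_n: float = 0.0
    emigration_c: float = 0.0
    emigration_n: float = 0.0
    growth_c: float = 0.0
    growth_n: float = 0.0
    immigration_c: float = 0.0
    immigration_n: float = 0.0
    thinning_kill_c: float = 0.0
    thinning_kill_n: float = 0.0


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _dev_rate(t_air, k_dd, t_base, t_opt, t_ceil):
    if t_air <= t_base:
        return 0.0
    if t_air <= t_opt:
        return (t_air - t_base) / k_dd
    if t_air >= t_ceil:
        return 0.0
    return (t_opt - t_base) / k_dd * (t_ceil - t_air) / (t_ceil - t_opt)


@njit(cache=True)
def _beta_fec(t, tmn, topt, tmx):
    if t <= tmn or t >= tmx:
        return 0.0
    return ((t - tmn) * (tmx - t)) / ((topt - tmn) * (tmx - topt))


@njit(cache=True)
def aphid_derivs(aph, t_air, lai_per_stem, conc_c, conc_n, n_stems,
                 ap, da, fx):
    """Per-stem stage derivatives ``da`` and per-area flux bundle ``fx``.

    ``aph`` holds the ten per-stem abundances; ``lai_per_stem`` is m2 leaf
    per stem; ``conc_c``/``conc_n`` are the phloem substrate concentrations
    (substrate per unit foliage structural C).
    """
    for i in range(N_APH):
        da[i] = 0.0
    for i in range(N_FLUX):
        fx[i] = 0.0

    imm = ap[AP_IMMIG]
    total = 0.0
    for i in range(N_APH):
        total += aph[i]
    if total <= 0.0 and imm <= 0.0:
        return   # extinction is absorbing (without background immigration)

    # food environment
    if lai_per_stem > 0.0 and conc_c > 0.0:
        sat_c = conc_c / (conc_c + ap[AP_KCONC])
        nc_ratio = conc_n / conc_c
        crowding = total / lai_per_stem
    else:
        sat_c = 0.0
        nc_ratio = 0.0
        crowding = 0.0
    crowd_f = 1.0 / (1.0 + crowding / ap[AP_CROWD_HALF])

    # per-capita intake, proportional to body C
    mc_a = ap[AP_MC_ADULT]
    upt_c = 0.0
    for m in range(2):
        for j in range(5):
            idx = m * 5 + j
            upt_c += aph[idx] * ap[AP_MFRAC + j]
    upt_c *= mc_a * ap[AP_INTAKE_REL] * sat_c * crowd_f   # kg C stem-1 d-1
    upt_n = upt_c * nc_ratio

    # development and reproduction demands
    dev = np.empty(4)
    for j in range(4):
        dev[j] = _dev_rate(t_air, ap[AP_K1 + j], ap[AP_TBASE],
                           ap[AP_TOPT_DEV], ap[AP_TCEIL])

    # fecundity of apterous adults from their realized N intake
    adult_n_intake = (mc_a * ap[AP_INTAKE_REL] * sat_c * crowd_f) * nc_ratio
    fec = (ap[AP_FECMAX] * adult_n_intake / (adult_n_intake + ap[AP_KFECN])
           * _beta_fec(t_air, ap[AP_TMINF], ap[AP_TOPTF], ap[AP_TMAXF]))
    births = aph[4] * fec   # apterous adults only

    growth_dem_c = births * ap[AP_MFRAC + 0] * mc_a
    for m in range(2):
        for j in range(4):
            idx = m * 5 + j
            dm = (ap[AP_MFRAC + j + 1] - ap[AP_MFRAC + j]) * mc_a
            growth_dem_c += dev[j] * aph[idx] * dm
    growth_dem_n = growth_dem_c * ap[AP_NC_BODY]

    # scale demography to what intake can pay for (starvation response)
    avail_c = upt_c * (1.0 - ap[AP_FRESP])
    scale = 1.0
    if growth_dem_c > 0.0:
        sc = avail_c / growth_dem_c
        if sc < scale:
            scale = sc
    if growth_dem_n > 0.0:
        sn = upt_n / growth_dem_n
        if sn < scale:
            scale = sn
    if scale < 0.0:
        scale = 0.0
    births *= scale
    growth_c = growth_dem_c * scale
    growth_n = growth_dem_n * scale

    # morph determination for newborns
    food_index = sat_c
    phi = crowding / (crowding + ap[AP_ALATE_HALF]) \
        + ap[AP_ALATE_BOOST] * (1.0 - food_index)
    if phi > 1.0:
        phi = 1.0
    elif phi < 0.0:
        phi = 0.0

    # mortality
    cold = ap[AP_TCOLD] - t_air
    mort_cold = ap[AP_CCOLD] * cold * cold if cold > 0.0 else 0.0
    ratio = sat_c * crowd_f / ap[AP_STARV_THRESH]
    if ratio > 1.0:
        ratio = 1.0
    mort_starv = ap[AP_MSTARV] * (1.0 - ratio)

    corpse_c = 0.0
    for m in range(2):
        base = m * 5
        prev_in = births * ((1.0 - phi) if m == 0 else phi)
        for j in range(5):
            idx = base + j
            mu = ap[AP_MORT0 + idx] + mort_cold + mort_starv
            out = dev[j] * scale * aph[idx] if j < 4 else 0.0
            da[idx] = prev_in - out - mu * aph[idx]
            corpse_c += mu * aph[idx] * ap[AP_MFRAC + j] * mc_a
            prev_in = out
    # alate adult emigration; immigrant alates passing through deposit
    # apterous nymphs at a constant background rate
    emig = ap[AP_EMIG] * aph[9]
    da[9] -= emig
    emig_c = emig * mc_a
    da[0] += imm
    imm_c = imm * ap[AP_MFRAC + 0] * mc_a

    resp_c = ap[AP_FRESP] * upt_c
    honey_c = upt_c - resp_c - growth_c
    if honey_c < 0.0:
        honey_c = 0.0
    excr_n = upt_n - growth_n
    if excr_n < 0.0:
        excr_n = 0.0

    # per-stem -> per-ground-area
    fx[FX_UPT_C] = upt_c * n_stems
    fx[FX_UPT_N] = upt_n * n_stems
    fx[FX_RESP] = resp_c * n_stems
    fx[FX_HONEY_C] = honey_c * n_stems
    fx[FX_EXCR_N] = excr_n * n_stems
    fx[FX_CORPSE_C] = corpse_c * n_stems
    fx[FX_CORPSE_N] = corpse_c * ap[AP_NC_BODY] * n_stems
    fx[FX_EMIG_C] = emig_c * n_stems
    fx[FX_EMIG_N] = emig_c * ap[AP_NC_BODY] * n_stems
    fx[FX_GROWTH_C] = growth_c * n_stems
    fx[FX_GROWTH_N] = growth_n * n_stems
    fx[FX_IMMIG_C] = imm_c * n_stems
    fx[FX_IMMIG_N] = imm_c * ap[AP_NC_BODY] * n_stems


# --------------------------------------------------------------------------
# operations (library surface)
# --------------------------------------------------------------------------

def development_rate(t_air: float, instar: int,
                     p: AphidParams | None = None) -> float:
    """Maturation rate (d-1) of one instar at a given air temperature."""
    p = p or AphidParams()
    if not 1 <= instar <= 4:
        raise ValueError("instar must be 1..4")
    return _dev_rate(float(t_air), p.thermal_k[instar - 1], p.t_base,
                     p.t_opt_dev, p.t_ceil_dev)


def per_capita_intake(c_conc: float, n_conc: float, crowding: float,
                      p: AphidParams | None = None,
                      stage: int = 5) -> tuple[float, float]:
    """(C, N) intake per aphid per day for stage 1..5 (5 = adult).

    Saturating in the phloem C concentration, reduced by crowding with
    half-saturation at ``crowd_half``; the N:C ratio of the intake equals
    the phloem's N:C ratio.
    """
    p = p or AphidParams()
    if c_conc < 0 or n_conc < 0 or crowding < 0:
        raise ValueError("inputs must be non-negative")
    if c_conc == 0.0:
        return 0.0, 0.0
    sat = c_conc / (c_conc + p.k_conc_c)
    crowd_f = 1.0 / (1.0 + crowding / p.crowd_half)
    ic = p.intake_rel * p.mass_frac[stage - 1] * p.mc_adult * sat * crowd_f
    return ic, ic * (n_conc / c_conc)


def fecundity(realized_n_intake: float, t_air: float,
              p: AphidParams | None = None) -> float:
    """Nymphs per apterous adult per day."""
    p = p or AphidParams()
    if realized_n_intake < 0:
        raise ValueError("intake must be non-negative")
    return (p.fec_max * realized_n_intake / (realized_n_intake + p.k_fec_n)
            * _beta_fec(float(t_air), p.t_min_fec, p.t_opt_fec, p.t_max_fec))


def alate_fraction(crowding: float, food_index: float,
                   p: AphidParams | None = None) -> float:
    """Fraction of births routed to the winged (alate) line.

    Non-decreasing in crowding (half-induction at ``alate_half`` when well
    fed) and non-increasing in food quality.
    """
    p = p or AphidParams()
    if crowding < 0 or not 0.0 <= food_index <= 1.0:
        raise ValueError("crowding >= 0 and food_index in [0,1] required")
    phi = (crowding / (crowding + p.alate_half)
           + p.alate_food_boost * (1.0 - food_index))
    return min(1.0, max(0.0, phi))


def mortality_rate(t_air: float, stage: int, intake_ratio: float,
                   p: AphidParams | None = None) -> float:
    """Per-capita mortality (d-1) for stage 1..10.

    Baseline + cold term (quadratic in the deficit below ``t_cold``) +
    starvation term rising linearly as the realized/demand intake ratio
    falls below ``starv_thresh``.
    """
    p = p or AphidParams()
    if not 1 <= stage <= N_APH:
        raise ValueError("stage must be 1..10")
    if not 0.0 <= intake_ratio <= 1.0:
        raise ValueError("intake_ratio must lie in [0, 1]")
    deficit = p.t_cold - t_air
    cold = p.c_cold * deficit * deficit if deficit > 0 else 0.0
    ratio = min(1.0, intake_ratio / p.starv_thresh)
    return p.mort_base[stage - 1] + cold + p.m_starv * (1.0 - ratio)


def aphid_odes(a: AphidState, w: WeatherInstant, lai_per_stem: float,
               conc_c: float, conc_n: float, n_stems: float,
               p: AphidParams | None = None
               ) -> tuple[np.ndarray, AphidFluxBundle]:
    """Time derivatives of the ten stages plus the C/N flux bundle."""
    p = p or AphidParams()
    if not np.all(np.isfinite(a.counts)):
        raise FloatingPointError("non-finite aphid state")
    da = np.zeros(N_APH)
    fx = np.zeros(N_FLUX)
    aphid_derivs(a.counts, w.T_air, float(lai_per_stem), float(conc_c),
                 float(conc_n), float(n_stems), p.pack(), da, fx)
    bundle = AphidFluxBundle(
        uptake_c=fx[FX_UPT_C], uptake_n=fx[FX_UPT_N],
        respiration_c=fx[FX_RESP], honeydew_c=fx[FX_HONEY_C],
        excreted_n=fx[FX_EXCR_N], corpse_c=fx[FX_CORPSE_C],
        corpse_n=fx[FX_CORPSE_N], emigration_c=fx[FX_EMIG_C],
        emigration_n=fx[FX_EMIG_N], growth_c=fx[FX_GROWTH_C],
        growth_n=fx[FX_GROWTH_N], immigration_c=fx[FX_IMMIG_C],
        immigration_n=fx[FX_IMMIG_N])
    return da, bundle


def inoculate(a: AphidState, density: float) -> AphidState:
    """Add ``density`` apterous adults per stem (the rotation-start inoculum)."""
    if density < 0:
        raise ValueError("inoculum density must be non-negative")
    counts = a.counts.copy()
    counts[4] += density
    return AphidState(counts)


def management_kill(a: AphidState, fraction_of_stems_removed: float,
                    n_stems: float, p: AphidParams | None = None
                    ) -> tuple[AphidState, float, float]:
    """Aphids on removed stems are killed and their biomass routed to soil.

    Per-stem abundances are unchanged (removed stems carry the average
    load); the per-ground-area population falls with the stems.  Returns the
    unchanged per-stem state and the killed (C, N) per ground area.
    """
    p = p or AphidParams()
    f = fraction_of_stems_removed
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    killed_c = f * n_stems * a.biomass_c(p)
    return replace(a, counts=a.counts.copy()), killed_c, killed_c * p.nc_body
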