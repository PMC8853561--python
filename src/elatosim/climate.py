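"""Deterministic diurnal + seasonal weather synthesis for an upland-Britain site.

The simulator is driven by a compact seasonal parameterization of the climate
at Eskdalemuir (55°19' N, 3°12' W, 242 m a.s.l.): for each driver (air
temperature, relative humidity, wind, rain, bright-sunshine fraction) the
annual course of the daily maximum and daily minimum is described by a
two-anchor curve through the driver's printed seasonal extremes, and the
diurnal course is reconstructed from the daily max/min with fixed phase
anchors (minimum temperature / minimum wind / maximum RH at dawn; the
opposite extreme at 15:00 local solar time).

Daily photosynthetically active radiation (PAR) is obtained from the
bright-sunshine fraction with the Angstrom regression
``j_PAR = j_extraterrestrial_PAR * (a + b * f_sun)`` and spread over the
daylight hours with a half-sine (sine-of-solar-elevation) profile.

Soil temperature is diurnally constant and equal to the mean of the daily
air-temperature extremes; rainfall is likewise constant within each day.

All times are days; day-of-year 1 = 1 January of a fixed 365-day
(climatological, non-leap) year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "SeasonalCurve",
    "SeasonalDriverSpec",
    "WeatherInstant",
    "ScenarioDelta",
    "day_of_year",
    "seasonal_daily",
    "diurnalize",
    "par_daily",
    "soil_temperature",
    "apply_scenario",
    "weather_at",
    "daily_from_monthly",
    "generate_forcing",
    "write_forcing_csv",
    "read_forcing_csv",
]

YEAR_DAYS = 365
SOLAR_CONSTANT = 1361.0          # W m-2
SECONDS_PER_DAY = 86400.0
FORCING_COLUMNS = ["time", "T_air", "T_soil", "RH", "PAR", "wind", "rain", "CO2"]

_MONTH_CUM = (0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334)


def day_of_year(month: int, day: int) -> int:
    """Day-of-year (1..365) for a calendar date in the fixed non-leap year."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return _MONTH_CUM[month - 1] + day


# --------------------------------------------------------------------------
# seasonal curves
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonalCurve:
    """Annual course of a daily statistic through two seasonal extremes.

    The curve passes through ``(day_hi, v_hi)`` and ``(day_lo, v_lo)`` and is
    interpolated between the anchors with half-cosine segments, so it is
    smooth at the extremes, periodic with period 365 d, and its annual mean
    is exactly ``(v_hi + v_lo) / 2``.  When the anchor days are antipodal
    (182.5 d apart) this is the plain sinusoid
    ``mean + amplitude * cos(2*pi*(d - day_hi)/365)``.
    """

    v_hi: float
    day_hi: float
    v_lo: float
    day_lo: float

    def __post_init__(self):
        if self.v_hi < self.v_lo:
            raise ValueError("seasonal curve requires v_hi >= v_lo")

    def value(self, day: float) -> float:
        return _seasonal_value(self.v_hi, self.day_hi, self.v_lo, self.day_lo, float(day))

    @property
    def mean(self) -> float:
        return 0.5 * (self.v_hi + self.v_lo)

    @property
    def amplitude(self) -> float:
        return 0.5 * (self.v_hi - self.v_lo)

    @classmethod
    def from_mean_amplitude(cls, mean: float, amplitude: float, day_hi: float) -> "SeasonalCurve":
        """Symmetric sinusoid: extremes at ``day_hi`` and 182.5 d later."""
        if amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        return cls(mean + amplitude, day_hi, mean - amplitude,
                   (day_hi + YEAR_DAYS / 2.0) % YEAR_DAYS)


@njit(cache=True)
def _seasonal_value(v_hi, day_hi, v_lo, day_lo, d):
    s = (d - day_hi) % YEAR_DAYS
    L1 = (day_lo - day_hi) % YEAR_DAYS
    if L1 == 0.0:
        return 0.5 * (v_hi + v_lo)
    L2 = YEAR_DAYS - L1
    if s <= L1:
        x = s / L1
        return v_lo + (v_hi - v_lo) * 0.5 * (1.0 + math.cos(math.pi * x))
    x = (s - L1) / L2
    return v_lo + (v_hi - v_lo) * 0.5 * (1.0 - math.cos(math.pi * x))


def daily_from_monthly(monthly: "np.ndarray | list[float]") -> np.ndarray:
    """Expand 12 monthly means to 365 daily values by linear interpolation.

    Monthly values are anchored at month mid-points (the convention used for
    climatological station tables) and interpolated linearly, wrapping across
    the year boundary.
    """
    m = np.asarray(monthly, dtype=float)
    if m.shape != (12,):
        raise ValueError("expected 12 monthly values")
    lengths = np.diff(np.append(_MONTH_CUM, YEAR_DAYS))
    mids = np.array(_MONTH_CUM) + (lengths + 1) / 2.0   # day-of-year of month centres
    days = np.arange(1, YEAR_DAYS + 1, dtype=float)
    # periodic linear interpolation
    xp = np.concatenate([mids - YEAR_DAYS, mids, mids + YEAR_DAYS])
    fp = np.concatenate([m, m, m])
    return np.interp(days, xp, fp)


# --------------------------------------------------------------------------
# driver specification
# --------------------------------------------------------------------------

def _eskdalemuir_curves() -> dict:
    d = day_of_year
    return dict(
        wind_max=SeasonalCurve(7.5, d(4, 26), 4.5, (d(4, 26) + 182.5) % YEAR_DAYS),
        wind_min=SeasonalCurve(2.5, d(4, 26), 1.5, (d(4, 26) + 182.5) % YEAR_DAYS),
        t_mean=SeasonalCurve(13.5, d(7, 16), 1.45, d(1, 16)),
        t_range=SeasonalCurve(5.0, d(5, 16), 2.15, d(12, 16)),
        rh_max=SeasonalCurve(0.91, d(12, 16), 0.75, d(5, 16)),
        rh_min=SeasonalCurve(0.88, d(12, 16), 0.65, d(5, 16)),
        rain=SeasonalCurve(5.65, d(1, 16), 2.8, d(5, 16)),
        sunshine=SeasonalCurve(0.32, d(6, 15), 0.19, d(12, 20)),
    )


@dataclass(frozen=True)
class SeasonalDriverSpec:
    """Site coordinates plus the seasonal curves of every weather driver.

    Units: temperatures °C, RH and sunshine fraction dimensionless in [0, 1],
    wind m s-1 at ``h_ref``, rain mm d-1.  Defaults reproduce the Eskdalemuir
    parameterization: wind daily max 6±1.5 / daily min 2±0.5 m s-1 peaking
    26 April; mean air temperature 1.45 °C (16 Jan) to 13.5 °C (16 Jul);
    diurnal temperature range 5 °C (16 May) to 2.15 °C (16 Dec); RH daily
    max 0.75 (16 May) to 0.91 (16 Dec), daily min 0.65 to 0.88; rain
    2.8 mm d-1 (16 May) to 5.65 mm d-1 (16 Jan); Angstrom a=0.19, b=0.62.
    """

    latitude: float = 55.317      # degrees N
    longitude: float = 3.2        # degrees W
    altitude: float = 242.0       # m a.s.l.
    a_ang: float = 0.19
    b_ang: float = 0.62
    h_ref: float = 50.0           # wind reference height, m
    par_fraction: float = 0.5     # PAR : total shortwave energy ratio
    co2_ambient: float = 350.0    # µmol mol-1
    wind_max: SeasonalCurve = field(default_factory=lambda: _eskdalemuir_curves()["wind_max"])
    wind_min: SeasonalCurve = field(default_factory=lambda: _eskdalemuir_curves()["wind_min"])
    t_mean: SeasonalCurve = field(default_factory=lambda: _eskdalemuir_curves()["t_mean"])
    t_range: SeasonalCurve = field(default_factory=lambda: _eskdalemuir_curves()["t_range"])
    rh_max: SeasonalCurve = field(default_factory=lambda: _eskdalemuir_curves()["rh_max"])
    rh_min: SeasonalCurve = field(default_factory=lambda: _eskdalemuir_curves()["rh_min"])
    rain: SeasonalCurve = field(default_factory=lambda: _eskdalemuir_curves()["rain"])
    sunshine: SeasonalCurve = field(default_factory=lambda: _eskdalemuir_curves()["sunshine"])

    def __post_init__(self):
        for name in ("rh_max", "rh_min", "sunshine"):
            c: SeasonalCurve = getattr(self, name)
            if not (0.0 <= c.v_lo and c.v_hi <= 1.0):
                raise ValueError(f"{name} curve must stay within [0, 1]")
        for name in ("wind_max", "wind_min", "rain"):
            if getattr(self, name).v_lo < 0:
                raise ValueError(f"{name} curve must be non-negative")
        days = np.arange(1, YEAR_DAYS + 1)
        wmax = np.array([self.wind_max.value(float(d)) for d in days])
        wmin = np.array([self.wind_min.value(float(d)) for d in days])
        if np.any(wmax < wmin):
            raise ValueError("wind daily max curve dips below daily min curve")
        rmax = np.array([self.rh_max.value(float(d)) for d in days])
        rmin = np.array([self.rh_min.value(float(d)) for d in days])
        if np.any(rmax < rmin):
            raise ValueError("RH daily max curve dips below daily min curve")

    def with_monthly(self, driver: str, monthly_max, monthly_min=None) -> "SeasonalDriverSpec":
        """Return a spec whose ``driver`` follows user-supplied monthly tables.

        Monthly station values are linearly interpolated to daily values (the
        original construction for this climate) and then least-squares
        summarized by the two-anchor curve through the interpolated annual
        extremes, preserving the extreme values and their dates.
        """
        dmax = daily_from_monthly(monthly_max)
        hi_d = int(np.argmax(dmax)) + 1
        lo_d = int(np.argmin(dmax)) + 1
        curve_hi = SeasonalCurve(float(dmax.max()), float(hi_d), float(dmax.min()), float(lo_d))
        mapping = {
            "wind": ("wind_max", "wind_min"),
            "rh": ("rh_max", "rh_min"),
            "rain": ("rain", None),
            "sunshine": ("sunshine", None),
            "t_mean": ("t_mean", None),
        }
        if driver not in mapping:
            raise ValueError(f"unknown driver {driver!r}")
        fmax, fmin = mapping[driver]
        kwargs = {fmax: curve_hi}
        if fmin is not None:
            if monthly_min is None:
                raise ValueError(f"driver {driver!r} needs monthly_min as well")
            dmin = daily_from_monthly(monthly_min)
            kwargs[fmin] = SeasonalCurve(float(dmin.max()), float(np.argmax(dmin)) + 1,
                                         float(dmin.min()), float(np.argmin(dmin)) + 1)
        return replace(self, **kwargs)

    # ---- packing for the compiled kernel --------------------------------
    def pack(self) -> np.ndarray:
        c = np.empty(N_CLIM, dtype=np.float64)
        c[CL_LAT] = self.latitude
        c[CL_ALT] = self.altitude
        c[CL_A_ANG] = self.a_ang
        c[CL_B_ANG] = self.b_ang
        c[CL_PAR_FRAC] = self.par_fraction
        c[CL_CO2_AMB] = self.co2_ambient
        for base, curve in (
            (CL_WMAX, self.wind_max), (CL_WMIN, self.wind_min),
            (CL_TMEAN, self.t_mean), (CL_TRANGE, self.t_range),
            (CL_RHMAX, self.rh_max), (CL_RHMIN, self.rh_min),
            (CL_RAIN, self.rain), (CL_SUN, self.sunshine),
        ):
            c[base:base + 4] = (curve.v_hi, curve.day_hi, curve.v_lo, curve.day_lo)
        return c


# packed-array layout (4 slots per curve: v_hi, day_hi, v_lo, day_lo)
CL_LAT, CL_ALT, CL_A_ANG, CL_B_ANG, CL_PAR_FRAC, CL_CO2_AMB = range(6)
CL_WMAX, CL_WMIN, CL_TMEAN, CL_TRANGE, CL_RHMAX, CL_RHMIN, CL_RAIN, CL_SUN = (
    6, 10, 14, 18, 22, 26, 30, 34)
N_CLIM = 38


# --------------------------------------------------------------------------
# instantaneous weather
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WeatherInstant:
    """Environmental drivers at one instant.

    ``par`` is an instantaneous rate expressed in daily-receipt units
    (J PAR m-2 d-1); integrating it over one day gives the daily receipt.
    """

    T_air: float      # °C
    T_soil: float     # °C
    RH: float         # fraction
    par: float        # J PAR m-2 d-1 (instantaneous rate)
    wind: float       # m s-1 at h_ref
    rain: float       # mm d-1
    co2: float        # µmol mol-1

    def __post_init__(self):
        if not (0.0 <= self.RH <= 1.0):
            raise ValueError("RH must lie in [0, 1]")
        if self.par < 0 or self.wind < 0 or self.rain < 0:
            raise ValueError("PAR, wind and rain must be non-negative")
        if self.co2 <= 0:
            raise ValueError("CO2 must be positive")


@dataclass(frozen=True)
class ScenarioDelta:
    """Climate-change scenario: temperature increment and CO2 level.

    ``dT`` is added to both air and soil temperature; ``co2`` replaces the
    ambient concentration.
    """

    dT: float = 0.0      # °C
    co2: float = 350.0   # µmol mol-1

    def __post_init__(self):
        if self.co2 <= 0:
            raise ValueError("CO2 must be positive")

    @property
    def label(self) -> str:
        return f"dT{self.dT:+g}_CO2{self.co2:g}"


def apply_scenario(w: WeatherInstant, delta: ScenarioDelta) -> WeatherInstant:
    """Shift air and soil temperature by ``delta.dT`` and set the CO2 level."""
    return replace(w, T_air=w.T_air + delta.dT, T_soil=w.T_soil + delta.dT,
                   co2=delta.co2)


# --------------------------------------------------------------------------
# solar geometry and kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _solar_geometry(lat_deg, doy):
    """Return (dawn hour, daylength hours, extraterrestrial receipt J m-2 d-1)."""
    phi = lat_deg * math.pi / 180.0
    decl = -23.44 * math.pi / 180.0 * math.cos(2.0 * math.pi * (doy + 10.0) / YEAR_DAYS)
    x = -math.tan(phi) * math.tan(decl)
    if x > 1.0:
        x = 1.0
    elif x < -1.0:
        x = -1.0
    ws = math.acos(x)
    daylength = 24.0 * ws / math.pi
    dawn = 12.0 - daylength / 2.0
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / YEAR_DAYS)
    ra = (SECONDS_PER_DAY / math.pi) * SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(decl)
        + math.cos(phi) * math.cos(decl) * math.sin(ws))
    if ra < 0.0:
        ra = 0.0
    return dawn, daylength, ra


@njit(cache=True)
def _diurnal_shape(dmax, dmin, hour, dawn):
    """Piecewise-cosine diurnal course: minimum at dawn, maximum at 15 h."""
    peak = 15.0
    if dawn <= hour <= peak:
        x = (hour - dawn) / (peak - dawn)
        return dmin + (dmax - dmin) * 0.5 * (1.0 - math.cos(math.pi * x))
    elapsed = (hour - peak) % 24.0
    L = (dawn - peak) % 24.0
    x = elapsed / L
    return dmax - (dmax - dmin) * 0.5 * (1.0 - math.cos(math.pi * x))


@njit(cache=True)
def _par_instant(j_daily, hour, dawn, daylength):
    dusk = dawn + daylength
    if hour <= dawn or hour >= dusk or daylength <= 0.0:
        return 0.0
    frac_day = daylength / 24.0
    return j_daily * (math.pi / 2.0) / frac_day * math.sin(
        math.pi * (hour - dawn) / daylength)


@njit(cache=True)
def weather_kernel(t, clim, dT, co2, out):
    """Fill ``out[0:7]`` with (T_air, T_soil, RH, PAR, wind, rain, CO2) at time t (d)."""
    day = math.floor(t)
    doy = day % YEAR_DAYS + 1.0
    hour = (t - day) * 24.0
    dawn, daylength, ra = _solar_geometry(clim[CL_LAT], doy)

    t_mean = _seasonal_value(clim[CL_TMEAN], clim[CL_TMEAN + 1],
                             clim[CL_TMEAN + 2], clim[CL_TMEAN + 3], doy)
    t_rng = _seasonal_value(clim[CL_TRANGE], clim[CL_TRANGE + 1],
                            clim[CL_TRANGE + 2], clim[CL_TRANGE + 3], doy)
    t_air = _diurnal_shape(t_mean + 0.5 * t_rng, t_mean - 0.5 * t_rng, hour, dawn) + dT
    t_soil = t_mean + dT

    rh_hi = _seasonal_value(clim[CL_RHMAX], clim[CL_RHMAX + 1],
                            clim[CL_RHMAX + 2], clim[CL_RHMAX + 3], doy)
    rh_lo = _seasonal_value(clim[CL_RHMIN], clim[CL_RHMIN + 1],
                            clim[CL_RHMIN + 2], clim[CL_RHMIN + 3], doy)
    # anti-phase: RH maximum at dawn, minimum at 15 h
    rh = rh_hi + rh_lo - _diurnal_shape(rh_hi, rh_lo, hour, dawn)
    if rh > 1.0:
        rh = 1.0
    elif rh < 0.0:
        rh = 0.0

    w_hi = _seasonal_value(clim[CL_WMAX], clim[CL_WMAX + 1],
                           clim[CL_WMAX + 2], clim[CL_WMAX + 3], doy)
    w_lo = _seasonal_value(clim[CL_WMIN], clim[CL_WMIN + 1],
                           clim[CL_WMIN + 2], clim[CL_WMIN + 3], doy)
    wind = _diurnal_shape(w_hi, w_lo, hour, dawn)

    rain = _seasonal_value(clim[CL_RAIN], clim[CL_RAIN + 1],
                           clim[CL_RAIN + 2], clim[CL_RAIN + 3], doy)

    f_sun = _seasonal_value(clim[CL_SUN], clim[CL_SUN + 1],
                            clim[CL_SUN + 2], clim[CL_SUN + 3], doy)
    j_daily = clim[CL_PAR_FRAC] * ra * (clim[CL_A_ANG] + clim[CL_B_ANG] * f_sun)
    par = _par_instant(j_daily, hour, dawn, daylength)

    out[0] = t_air
    out[1] = t_soil
    out[2] = rh
    out[3] = par
    out[4] = wind
    out[5] = rain
    out[6] = co2


# --------------------------------------------------------------------------
# operations (library surface)
# --------------------------------------------------------------------------

def seasonal_daily(spec: SeasonalDriverSpec, doy: int) -> dict:
    """Per-driver daily max/min (plus daily rain, sunshine fraction) for one day.

    Raises ``ValueError`` unless ``1 <= doy <= 365``.
    """
    if not 1 <= int(doy) <= YEAR_DAYS:
        raise ValueError(f"day of year out of range: {doy}")
    d = float(doy)
    t_mean = spec.t_mean.value(d)
    t_rng = spec.t_range.value(d)
    return {
        "T_air": (t_mean + 0.5 * t_rng, t_mean - 0.5 * t_rng),
        "RH": (spec.rh_max.value(d), spec.rh_min.value(d)),
        "wind": (spec.wind_max.value(d), spec.wind_min.value(d)),
        "rain": spec.rain.value(d),
        "sunshine": spec.sunshine.value(d),
    }


def diurnalize(daily_max: float, daily_min: float, hour: float,
               dawn_hour: float, phase: str = "in_phase") -> float:
    """Instantaneous value from daily extremes with dawn/15 h phase anchors.

    ``in_phase`` drivers (temperature, wind) take their minimum at dawn and
    their maximum at 15 h; ``anti_phase`` (RH) the reverse.  The shape is a
    continuous piecewise cosine bounded by [daily_min, daily_max].
    """
    if daily_max < daily_min:
        raise ValueError("daily_max < daily_min")
    if not 0.0 <= hour < 24.0:
        raise ValueError("hour must lie in [0, 24)")
    v = _diurnal_shape(daily_max, daily_min, hour, dawn_hour)
    if phase == "in_phase":
        return v
    if phase == "anti_phase":
        return daily_max + daily_min - v
    raise ValueError(f"unknown phase {phase!r}")


def par_daily(spec: SeasonalDriverSpec, doy: int, sunshine_fraction: float) -> float:
    """Daily PAR receipt (J m-2 d-1) from the Angstrom sunshine regression."""
    if not 0.0 <= sunshine_fraction <= 1.0:
        raise ValueError("sunshine fraction must lie in [0, 1]")
    if not 1 <= int(doy) <= YEAR_DAYS:
        raise ValueError(f"day of year out of range: {doy}")
    _, _, ra = _solar_geometry(spec.latitude, float(doy))
    return spec.par_fraction * ra * (spec.a_ang + spec.b_ang * sunshine_fraction)


def extraterrestrial_par(spec: SeasonalDriverSpec, doy: int) -> float:
    """Extraterrestrial PAR receipt (J m-2 d-1) for the site latitude."""
    _, _, ra = _solar_geometry(spec.latitude, float(doy))
    return spec.par_fraction * ra


def dawn_hour(spec: SeasonalDriverSpec, doy: int) -> float:
    """Hour of dawn (local solar time) at the site for a given day."""
    dawn, _, _ = _solar_geometry(spec.latitude, float(doy))
    return dawn


def soil_temperature(daily_T_air_max: float, daily_T_air_min: float) -> float:
    """Diurnally constant soil temperature = mean of daily air extremes."""
    if daily_T_air_max < daily_T_air_min:
        raise ValueError("daily max below daily min")
    return 0.5 * (daily_T_air_max + daily_T_air_min)


def weather_at(spec: SeasonalDriverSpec, t: float,
               delta: ScenarioDelta | None = None) -> WeatherInstant:
    """Instantaneous weather at simulation time ``t`` (days since 1 Jan)."""
    d = delta or ScenarioDelta(0.0, spec.co2_ambient)
    out = np.empty(7)
    weather_kernel(float(t), spec.pack(), d.dT, d.co2, out)
    return WeatherInstant(*out)


# --------------------------------------------------------------------------
# forcing series I/O
# --------------------------------------------------------------------------

def generate_forcing(spec: SeasonalDriverSpec, steps_per_day: int = 48,
                     days: int = YEAR_DAYS,
                     delta: ScenarioDelta | None = None) -> pd.DataFrame:
    """Tabulate the generated drivers on a uniform sub-daily grid."""
    d = delta or ScenarioDelta(0.0, spec.co2_ambient)
    clim = spec.pack()
    n = days * steps_per_day
    times = np.arange(n) / steps_per_day
    rows = np.empty((n, 7))
    buf = np.empty(7)
    for i, t in enumerate(times):
        weather_kernel(t, clim, d.dT, d.co2, buf)
        rows[i] = buf
    df = pd.DataFrame(rows, columns=FORCING_COLUMNS[1:])
    df.insert(0, "time", times)
    return df


def write_forcing_csv(df: pd.DataFrame, path) -> None:
    if list(df.columns) != FORCING_COLUMNS:
        raise ValueError(f"forcing frame must have columns {FORCING_COLUMNS}")
    df.to_csv(path, index=False)


def read_forcing_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"forcing CSV missing columns: {missing}")
    df = df[FORCING_COLUMNS]
    t = df["time"].to_numpy()
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("forcing time column must be strictly increasing")
    return df
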