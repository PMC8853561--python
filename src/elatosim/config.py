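"""YAML configuration surface.

One structured file configures the whole tool.  Every section is optional;
omitted keys fall back to the built-in Eskdalemuir / standard-management
defaults.  Precedence is CLI overrides > config file > defaults.

Schema (all units SI-with-days as used throughout the package)::

    site:            # SeasonalDriverSpec scalars
      latitude: 55.317
      a_ang: 0.19
      ...
    climate:         # seasonal curves; each is {v_hi, day_hi, v_lo, day_lo}
      wind_max: {v_hi: 7.5, day_hi: 116, v_lo: 4.5, day_lo: 298.5}
      ...            # or {mean, amplitude, day_hi} for a plain sinusoid
    stand:           # StandParams fields
      g_wood: 0.0032
    aphids:          # AphidParams fields (tuples as lists)
      c_cold: 0.055
    management:      # ManagementSchedule fields
      thinnings: [[20, 0.45], [25, 0.40]]
    sim:             # SimConfig fields
      maxt: 0.020833333
      aphids_on: true
    scenario:
      dT: 0.0
      co2: 350.0
    grid:            # scenario grid for --grid runs
      dT: [-2, -1, 0, 1, 2, 3]
      co2: [350, 700]
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .aphids import AphidParams
from .climate import ScenarioDelta, SeasonalCurve, SeasonalDriverSpec
from .engine import SimConfig
from .stand import ManagementSchedule, StandParams

__all__ = [
    "RunSettings",
    "load_config",
    "default_settings",
    "dump_default_config",
    "config_hash",
    "DEFAULT_GRID",
]

DEFAULT_GRID = {"dT": [-2.0, -1.0, 0.0, 1.0, 2.0, 3.0],
                "co2": [350.0, 700.0]}

_CURVE_FIELDS = ("wind_max", "wind_min", "t_mean", "t_range",
                 "rh_max", "rh_min", "rain", "sunshine")
_SITE_FIELDS = ("latitude", "longitude", "altitude", "a_ang", "b_ang",
                "h_ref", "par_fraction", "co2_ambient")


@dataclass
class RunSettings:
    """Fully resolved configuration for a run or a scenario grid."""

    climate: SeasonalDriverSpec = field(default_factory=SeasonalDriverSpec)
    stand: StandParams = field(default_factory=StandParams)
    aphids: AphidParams = field(default_factory=AphidParams)
    management: ManagementSchedule = field(default_factory=ManagementSchedule)
    sim: SimConfig = field(default_factory=SimConfig)
    scenario: ScenarioDelta = field(default_factory=ScenarioDelta)
    grid: dict = field(default_factory=lambda: dict(DEFAULT_GRID))

    def to_dict(self) -> dict:
        d = {
            "site": {k: getattr(self.climate, k) for k in _SITE_FIELDS},
            "climate": {k: dataclasses.asdict(getattr(self.climate, k))
                        for k in _CURVE_FIELDS},
            "stand": dataclasses.asdict(self.stand),
            "aphids": dataclasses.asdict(self.aphids),
            "management": dataclasses.asdict(self.management),
            "sim": dataclasses.asdict(self.sim),
            "scenario": {"dT": self.scenario.dT, "co2": self.scenario.co2},
            "grid": {k: list(v) for k, v in self.grid.items()},
        }
        return _plainify(d)


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if hasattr(obj, "item"):
        obj = obj.item()
    if isinstance(obj, bool) or obj is None or isinstance(obj, str):
        return obj
    if isinstance(obj, (int, float)):
        return float(obj)   # stable numeric form for hashing
    return obj


def default_settings() -> RunSettings:
    return RunSettings()


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


def _check_keys(section: str, given: dict, allowed) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}': {sorted(unknown)}")


def _curve_from_dict(name: str, d: dict) -> SeasonalCurve:
    if {"mean", "amplitude", "day_hi"} <= set(d):
        _check_keys(f"climate.{name}", d, ("mean", "amplitude", "day_hi"))
        return SeasonalCurve.from_mean_amplitude(
            float(d["mean"]), float(d["amplitude"]), float(d["day_hi"]))
    _check_keys(f"climate.{name}", d, ("v_hi", "day_hi", "v_lo", "day_lo"))
    try:
        return SeasonalCurve(float(d["v_hi"]), float(d["day_hi"]),
                             float(d["v_lo"]), float(d["day_lo"]))
    except KeyError as e:
        raise ConfigError(f"climate.{name} missing {e}") from e


def _dataclass_update(section: str, cls, base, updates: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    _check_keys(section, updates, names)
    kwargs = {f.name: getattr(base, f.name) for f in dataclasses.fields(cls)}
    for k, v in updates.items():
        if isinstance(kwargs[k], tuple) and isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid '{section}' configuration: {e}") from e


def load_config(path=None, overrides: dict | None = None) -> RunSettings:
    """Resolve a run configuration from a YAML file plus override dict.

    ``overrides`` uses the same section/key structure as the file and wins
    over it; both win over the built-in defaults.  Unknown sections or keys
    raise :class:`ConfigError`.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        raw = loaded
    for sec, vals in (overrides or {}).items():
        raw.setdefault(sec, {})
        if isinstance(vals, dict):
            raw[sec] = {**raw[sec], **vals}
        else:
            raw[sec] = vals

    _check_keys("config", raw, ("site", "climate", "stand", "aphids",
                                "management", "sim", "scenario", "grid"))
    s = RunSettings()

    site = raw.get("site", {})
    _check_keys("site", site, _SITE_FIELDS)
    climate_curves = raw.get("climate", {})
    _check_keys("climate", climate_curves, _CURVE_FIELDS)
    curve_kwargs = {name: _curve_from_dict(name, d)
                    for name, d in climate_curves.items()}
    try:
        s.climate = dataclasses.replace(
            s.climate, **{k: float(v) for k, v in site.items()}, **curve_kwargs)
    except ValueError as e:
        raise ConfigError(f"invalid climate configuration: {e}") from e

    if "stand" in raw:
        s.stand = _dataclass_update("stand", StandParams, s.stand, raw["stand"])
    if "aphids" in raw:
        s.aphids = _dataclass_update("aphids", AphidParams, s.aphids,
                                     raw["aphids"])
    if "management" in raw:
        s.management = _dataclass_update("management", ManagementSchedule,
                                         s.management, raw["management"])
    if "sim" in raw:
        s.sim = _dataclass_update("sim", SimConfig, s.sim, raw["sim"])
    if "scenario" in raw:
        sc = raw["scenario"]
        _check_keys("scenario", sc, ("dT", "co2"))
        try:
            s.scenario = ScenarioDelta(float(sc.get("dT", 0.0)),
                                       float(sc.get("co2", 350.0)))
        except ValueError as e:
            raise ConfigError(f"invalid scenario: {e}") from e
    if "grid" in raw:
        g = raw["grid"]
        _check_keys("grid", g, ("dT", "co2"))
        s.grid = {"dT": [float(v) for v in g.get("dT", DEFAULT_GRID["dT"])],
                  "co2": [float(v) for v in g.get("co2", DEFAULT_GRID["co2"])]}
    return s


def dump_default_config(path) -> None:
    """Write the fully resolved default configuration as YAML."""
    Path(path).write_text(
        yaml.safe_dump(default_settings().to_dict(), sort_keys=True))


def config_hash(settings: RunSettings) -> str:
    """Deterministic short hash of a resolved configuration."""
    blob = json.dumps(settings.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
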