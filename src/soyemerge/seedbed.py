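"""Virtual seedbeds: seed placement, aggregates, soil layers and crust state.

A seedbed is the tilled surface layer (0-10 cm here) into which seeds are
sown.  Seeds receive random depths from a configurable sowing-depth
distribution; soil aggregates (clods) are described by diameter classes with
areal densities and may lie on the surface or be buried.  Soil water state
is supplied per day for three fixed layers (0-3, 3-5 and 5-10 cm), together
with soil temperature at sowing depth and rainfall.

Surface crusting is driven by cumulative rainfall after sowing: once the
cumulative total passes a class-specific threshold the crust is present for
the rest of the horizon, and each crust day is labelled wet or dry from that
day's rainfall.  Non-crusting (clay) seedbeds never form a crust.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigError, InputError

#: Fixed soil layer bounds (cm): 0-3, 3-5, 5-10.
LAYER_BOUNDS: tuple[tuple[float, float], ...] = ((0.0, 3.0), (3.0, 5.0), (5.0, 10.0))

SEEDBED_DEPTH_CM = 10.0

CRUSTING_CLASSES = ("non_crusting", "moderately_crusting", "highly_crusting")

#: Default cumulative-rainfall thresholds (mm) for crust formation, by class.
#: These are calibration knobs, not measured constants.
CRUST_THRESHOLD_DEFAULTS: dict[str, float] = {
    "non_crusting": math.inf,
    "moderately_crusting": 25.0,
    "highly_crusting": 15.0,
}

# crust_state codes
CRUST_ABSENT, CRUST_DRY, CRUST_WET = 0, 1, 2


def layer_index(depth_cm: float) -> int:
    """Map a depth to its soil layer index (0-3 / 3-5 / 5-10 cm).

    Depths beyond 10 cm are clamped to the deepest layer.
    """
    if depth_cm < LAYER_BOUNDS[0][1]:
        return 0
    if depth_cm < LAYER_BOUNDS[1][1]:
        return 1
    return 2


@dataclass
class AggregateClass:
    """One aggregate size class: diameter (cm), areal density, position."""

    diameter_cm: float
    count_per_m2: float
    surface: bool = False

    def __post_init__(self):
        if self.diameter_cm <= 0:
            raise ConfigError("aggregate diameter must be positive")
        if self.count_per_m2 < 0:
            raise ConfigError("aggregate count must be >= 0")


@dataclass
class SeedbedConfig:
    """Configuration of a virtual seedbed and its sowing operation.

    The sowing-depth distribution is either a truncated normal
    (``depth_mean``, ``depth_sd``, truncated to ``depth_bounds``) or, if
    ``depth_classes`` is given, a discrete distribution over depth classes
    (cm -> probability).
    """

    n_seeds: int = 1000
    depth_mean: float = 3.0
    depth_sd: float = 0.7
    depth_bounds: tuple[float, float] = (1.0, 6.0)
    depth_classes: dict[float, float] | None = None
    aggregate_spec: list[AggregateClass] = field(default_factory=list)
    soil_crusting_class: str = "non_crusting"
    crust_rainfall_threshold: float | None = None
    crust_wet_rain_mm: float = 2.0

    def __post_init__(self):
        if self.n_seeds <= 0:
            raise ConfigError("n_seeds must be positive")
        if self.soil_crusting_class not in CRUSTING_CLASSES:
            raise ConfigError(f"unknown crusting class {self.soil_crusting_class!r}")
        if self.depth_classes is not None:
            if not self.depth_classes:
                raise ConfigError("empty sowing-depth distribution")
            total = sum(self.depth_classes.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"depth-class probabilities sum to {total}, not 1")
            if any(d < 0.5 or d > SEEDBED_DEPTH_CM for d in self.depth_classes):
                raise ConfigError("depth classes must lie within [0.5, 10] cm")
        else:
            lo, hi = self.depth_bounds
            if not (0.5 <= lo < hi <= SEEDBED_DEPTH_CM):
                raise ConfigError("depth bounds must satisfy 0.5 <= lo < hi <= 10 cm")
            if self.depth_sd <= 0:
                raise ConfigError("depth_sd must be positive")
        self.aggregate_spec = [
            a if isinstance(a, AggregateClass) else AggregateClass(**a)
            for a in self.aggregate_spec
        ]

    @property
    def effective_crust_threshold(self) -> float:
        if self.crust_rainfall_threshold is not None:
            return self.crust_rainfall_threshold
        return CRUST_THRESHOLD_DEFAULTS[self.soil_crusting_class]

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_seeds": self.n_seeds,
            "depth_mean": self.depth_mean,
            "depth_sd": self.depth_sd,
            "depth_bounds": list(self.depth_bounds),
            "depth_classes": (
                {str(k): v for k, v in self.depth_classes.items()}
                if self.depth_classes else None
            ),
            "aggregate_spec": [
                {"diameter_cm": a.diameter_cm, "count_per_m2": a.count_per_m2,
                 "surface": a.surface}
                for a in self.aggregate_spec
            ],
            "soil_crusting_class": self.soil_crusting_class,
            "crust_rainfall_threshold": self.crust_rainfall_threshold,
            "crust_wet_rain_mm": self.crust_wet_rain_mm,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SeedbedConfig":
        d = dict(d)
        if d.get("depth_classes"):
            d["depth_classes"] = {float(k): v for k, v in d["depth_classes"].items()}
        if "depth_bounds" in d and d["depth_bounds"] is not None:
            d["depth_bounds"] = tuple(d["depth_bounds"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SeedbedConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class WeatherSeries:
    """Daily seedbed weather since sowing (day 1 = first day after sowing).

    ``psi`` has one column per soil layer (0-3, 3-5, 5-10 cm); water
    potentials are in MPa (<= 0), soil temperature in deg C at sowing depth,
    rainfall in mm/day.
    """

    soil_temp: np.ndarray
    rainfall: np.ndarray
    psi: np.ndarray  # shape (n_days, 3)

    def __post_init__(self):
        self.soil_temp = np.asarray(self.soil_temp, dtype=float)
        self.rainfall = np.asarray(self.rainfall, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        n = len(self.soil_temp)
        if len(self.rainfall) != n or self.psi.shape != (n, 3):
            raise InputError("weather arrays must share the same number of days")
        if np.any(~np.isfinite(self.soil_temp)) or np.any(~np.isfinite(self.psi)):
            raise InputError("weather series contains missing values")
        if np.any(self.psi > 1e-12):
            raise InputError("water potentials must be <= 0 MPa")
        if np.any(self.rainfall < 0):
            raise InputError("rainfall must be >= 0")

    @property
    def n_days(self) -> int:
        return len(self.soil_temp)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "day": np.arange(1, self.n_days + 1),
            "soil_temp_sowing_depth_C": self.soil_temp,
            "rainfall_mm": self.rainfall,
            "psi_0_3_MPa": self.psi[:, 0],
            "psi_3_5_MPa": self.psi[:, 1],
            "psi_5_10_MPa": self.psi[:, 2],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        df = pd.read_csv(path)
        required = {
            "day", "soil_temp_sowing_depth_C", "rainfall_mm",
            "psi_0_3_MPa", "psi_3_5_MPa", "psi_5_10_MPa",
        }
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"weather CSV missing columns: {sorted(missing)}")
        df = df.sort_values("day")
        days = df["day"].to_numpy()
        if not np.array_equal(days, np.arange(1, len(days) + 1)):
            raise InputError("weather CSV must cover days 1..N without gaps")
        return cls(
            soil_temp=df["soil_temp_sowing_depth_C"].to_numpy(),
            rainfall=df["rainfall_mm"].to_numpy(),
            psi=df[["psi_0_3_MPa", "psi_3_5_MPa", "psi_5_10_MPa"]].to_numpy(),
        )


@dataclass
class Seedbed:
    """A realised virtual seedbed: sown seeds, aggregates, daily crust state."""

    seed_depths: np.ndarray
    aggregate_classes: list[AggregateClass]
    aggregates: list[tuple[float, float, bool]]  # (diameter, depth, surface) sample / m^2
    config: SeedbedConfig
    crust_state: np.ndarray | None = None  # per-day codes, filled by update_crust

    @property
    def n_seeds(self) -> int:
        return len(self.seed_depths)


def build_seedbed(cfg: SeedbedConfig, rng_seed) -> Seedbed:
    """Place seeds and aggregates at random according to the configuration.

    Seed depths are i.i.d. draws from the configured sowing-depth
    distribution.  Aggregates are instantiated for one square metre of
    seedbed (buried ones with uniform random depth, surface ones at depth 0)
    as a concrete realisation; the emergence engine works from the areal
    densities in ``aggregate_classes``.  Deterministic given ``rng_seed``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if cfg.depth_classes is not None:
        depths_arr = np.array(sorted(cfg.depth_classes))
        probs = np.array([cfg.depth_classes[d] for d in depths_arr])
        depths = rng.choice(depths_arr, size=cfg.n_seeds, p=probs)
    else:
        lo, hi = cfg.depth_bounds
        a = (lo - cfg.depth_mean) / cfg.depth_sd
        b = (hi - cfg.depth_mean) / cfg.depth_sd
        depths = stats.truncnorm.rvs(
            a, b, loc=cfg.depth_mean, scale=cfg.depth_sd,
            size=cfg.n_seeds, random_state=rng,
        )
    aggregates: list[tuple[float, float, bool]] = []
    for ac in cfg.aggregate_spec:
        n = rng.poisson(ac.count_per_m2)
        for _ in range(n):
            depth = 0.0 if ac.surface else float(rng.uniform(0.0, SEEDBED_DEPTH_CM))
            aggregates.append((ac.diameter_cm, depth, ac.surface))
    return Seedbed(
        seed_depths=np.asarray(depths, dtype=float),
        aggregate_classes=list(cfg.aggregate_spec),
        aggregates=aggregates,
        config=cfg,
    )


def update_crust(
    seedbed: Seedbed, weather: WeatherSeries, cfg: SeedbedConfig | None = None
) -> Seedbed:
    """Fill the seedbed's daily crust state from the rainfall series.

    The crust appears on the first day cumulative rainfall since sowing
    reaches the crusting threshold and persists for the rest of the horizon;
    each crust day is wet if that day's rainfall is at least
    ``crust_wet_rain_mm``, else dry.  Non-crusting soils stay crust-free.
    """
    cfg = cfg or seedbed.config
    cum = np.cumsum(weather.rainfall)
    present = cum >= cfg.effective_crust_threshold
    wet = weather.rainfall >= cfg.crust_wet_rain_mm
    state = np.where(present, np.where(wet, CRUST_WET, CRUST_DRY), CRUST_ABSENT)
    seedbed.crust_state = state.astype(np.int8)
    return seedbed


def seedbed_water_status(weekly_rainfall_mm: float) -> str:
    """Classify seedbed water status from weekly cumulative rainfall.

    At least 10 mm of cumulative rainfall over the week rules out water
    stress in the seedbed (``"no_stress"``); otherwise stress is possible.
    """
    if weekly_rainfall_mm < 0:
        raise InputError("weekly rainfall must be >= 0")
    return "no_stress" if weekly_rainfall_mm >= 10.0 else "possible_stress"
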