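"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the data the pipeline consumes:

* laboratory germination time courses governed by a known thermal-time
  distribution, base temperature and (for osmotic series) a per-seed base
  water potential, with binomial sampling noise from finite replicates;
* daily seedbed weather (soil temperature, rainfall, layer water
  potentials) from a handful of named templates;
* seedbed configuration templates keyed by soil type.

Because every generated dataset is governed by explicit true parameters,
estimation and simulation can be tested as round trips: feed generated data
through the stack and compare the recovered parameters with the generating
ones.

Cultivar parameter presets (``preset_cultivar_params``) encode published
laboratory values for three soybean cultivars — base temperatures of 4, 3
and 3.5 deg C, optimum temperatures of 28-30 deg C, mean base water
potentials of -0.58 to -0.71 MPa, germinable fractions of 0.97-0.99 and a
median thermal time to germination of 18 deg C day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .germination import (
    CultivarGerminationParams,
    GerminationTimeCourse,
    ThermalTimeDistribution,
)
from .seedbed import AggregateClass, SeedbedConfig, WeatherSeries

#: Temperatures used in the laboratory incubation design (deg C).
LAB_TEMPERATURES = (3.0, 6.5, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 37.5, 40.0, 43.0)

#: Water potentials of the osmotic (PEG) series, tested at 20 deg C (MPa).
LAB_POTENTIALS = (0.0, -0.10, -0.25, -0.50)


# ---------------------------------------------------------------------------
# Cultivar presets
# ---------------------------------------------------------------------------

def thermal_time_distribution_from_median(
    median_Cd: float = 18.0, k: float = 0.35,
    class_width: float = 5.0, upper: float = 60.0,
) -> ThermalTimeDistribution:
    """Gompertz-shaped thermal-time distribution with a given median.

    With the default shape parameter nearly all mass falls below 40 deg C
    day, matching rapid soybean germination.
    """
    tm = median_Cd - (-math.log(math.log(2.0))) / k
    return ThermalTimeDistribution.from_gompertz(1.0, k, tm, class_width, upper)


_PRESETS = {
    # name: (Tb, Topt, psi_b_mean, germinable_fraction)
    "Ecudor": (4.0, 28.0, -0.58, 0.97),
    "Isidor": (3.0, 30.0, -0.56, 0.99),
    "Santana": (3.5, 30.0, -0.71, 0.97),
}


def preset_cultivar_params(name: str) -> CultivarGerminationParams:
    """Published lab germination parameters for one of three soybean cultivars."""
    if name not in _PRESETS:
        raise ConfigError(f"unknown cultivar preset {name!r}; choose from {sorted(_PRESETS)}")
    Tb, Topt, psi_b, gf = _PRESETS[name]
    # per-percentile spread of 0.35 MPa: fast percentiles carry the most
    # negative base potential (published span runs from -0.75 MPa for the
    # fastest seeds to -0.50 MPa for the slowest), centred on the mean over
    # the six percentiles
    from .germination import PERCENTILES
    centre = float(np.mean(PERCENTILES))
    by_p = {p: psi_b + 0.35 * (p - centre) / 100.0 for p in PERCENTILES}
    return CultivarGerminationParams(
        name=name, Tb=Tb, Topt=Topt, psi_b_mean=psi_b,
        psi_b_by_percentile={p: min(v, 0.0) for p, v in by_p.items()},
        germinable_fraction=gf,
        thermal_time_distribution=thermal_time_distribution_from_median(),
    )


# ---------------------------------------------------------------------------
# Laboratory time courses
# ---------------------------------------------------------------------------

def _psi_b_of_quantile(params: CultivarGerminationParams, u: np.ndarray) -> np.ndarray:
    """Per-seed base water potential, comonotone with germination speed.

    Fast-germinating seeds (low u) carry the most negative base potential;
    values interpolate the per-percentile map, or fall back to the mean when
    no spread is given.
    """
    if len(params.psi_b_by_percentile) >= 2:
        ps = np.array(sorted(params.psi_b_by_percentile))
        vs = np.array([params.psi_b_by_percentile[p] for p in ps])
        return np.interp(u * 100.0, ps, vs)
    return np.full_like(u, params.psi_b_mean)


def generate_time_courses(
    true_params: CultivarGerminationParams,
    temperatures: tuple[float, ...] = (),
    potentials: tuple[float, ...] = (),
    n_seeds: int = 25,
    n_replicates: int = 4,
    rng_seed: int | np.random.SeedSequence = 0,
    obs_interval_h: float = 8.0,
    max_days: float = 21.0,
    potentials_temperature: float = 20.0,
) -> list[GerminationTimeCourse]:
    """Simulate replicated Petri-dish germination courses with known truth.

    Each seed draws a germination-speed quantile ``u``; its thermal-time
    requirement is the ``u``-quantile of the true distribution and, for
    osmotic series, its base water potential is comonotone with ``u``.  At
    temperature T the germination hour is requirement / (T - Tb) x 24; at
    water potential psi (held at 20 deg C) the rate is further scaled by
    ``(psi - psi_b) / (0 - psi_b)`` clipped at zero, the linear
    rate-reduction consistent with x-intercept estimation.  Non-germinable
    seeds (Bernoulli) never germinate; scoring happens every
    ``obs_interval_h`` hours (three times a day by default) until no further
    germination is expected, capped at ``max_days`` (a three-week Petri-dish
    assay by default, after which stalled dishes are closed).

    Temperatures at or below the base temperature yield all-zero counts —
    that is the definition of the base temperature, not an error.
    """
    rng = np.random.default_rng(rng_seed)
    courses: list[GerminationTimeCourse] = []
    dist = true_params.thermal_time_distribution

    def make_course(level_type, level_value, hour_fn):
        rep_hours = []
        for _ in range(n_replicates):
            u = rng.random(n_seeds)
            germinable = rng.random(n_seeds) < true_params.germinable_fraction
            hours = hour_fn(u)
            hours = np.where(germinable, hours, np.inf)
            rep_hours.append(hours)
        finite = np.concatenate(rep_hours)
        finite = finite[np.isfinite(finite)]
        if finite.size:
            t_end = min(float(finite.max()) * 1.1 + obs_interval_h, max_days * 24.0)
        else:
            t_end = 10.0 * 24.0
        grid = np.arange(obs_interval_h, t_end + obs_interval_h, obs_interval_h)
        observations = [
            [(float(t), int(np.sum(h <= t))) for t in grid] for h in rep_hours
        ]
        return GerminationTimeCourse(
            level_type=level_type, level_value=level_value,
            seeds_per_replicate=n_seeds, observations=observations,
        )

    for T in temperatures:
        if T <= true_params.Tb:
            def hour_fn(u, T=T):
                return np.full_like(u, np.inf)
        else:
            def hour_fn(u, T=T):
                req = np.asarray(dist.quantile(u))
                return req / (T - true_params.Tb) * 24.0
        courses.append(make_course("temperature", float(T), hour_fn))

    T0 = potentials_temperature
    for psi in potentials:
        def hour_fn(u, psi=psi):
            req = np.asarray(dist.quantile(u))
            base_hours = req / (T0 - true_params.Tb) * 24.0
            psi_b = _psi_b_of_quantile(true_params, u)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.clip((psi - psi_b) / (0.0 - psi_b), 0.0, None)
                hours = np.where(f > 0, base_hours / np.where(f > 0, f, 1.0), np.inf)
            return hours
        courses.append(make_course("water_potential", float(psi), hour_fn))

    return courses


# ---------------------------------------------------------------------------
# Weather generator
# ---------------------------------------------------------------------------

@dataclass
class WeatherTemplate:
    mean_temp: float
    temp_sd: float
    temp_ar1: float
    rain_prob: float
    rain_shape: float
    rain_scale: float
    start_wetness: float = 0.9


#: Template anchors: spring sowing-depth temperatures of 11-17 deg C and
#: 30-day rainfall totals of roughly 34-125 mm frame the wet templates.
WEATHER_TEMPLATES: dict[str, WeatherTemplate] = {
    "warm_wet": WeatherTemplate(16.0, 2.0, 0.6, 0.50, 1.2, 4.0),
    "cold_wet": WeatherTemplate(11.0, 2.0, 0.6, 0.50, 1.2, 4.0),
    "warm_dry_spell": WeatherTemplate(16.0, 2.0, 0.6, 0.12, 1.2, 3.0,
                                      start_wetness=0.55),
    "crust_prone": WeatherTemplate(14.0, 2.0, 0.6, 0.60, 1.5, 6.0),
}

# layer-specific drying and recharge rates (0-3 cm dries fastest)
_DRY_RATE = np.array([0.18, 0.12, 0.07])
_RECHARGE = np.array([0.9, 0.6, 0.4])
_PSI_MIN = -1.5  # MPa at fully dry


def _potentials_from_rain(rainfall: np.ndarray, start_wetness: float) -> np.ndarray:
    """Layer water potentials from a rainfall series via a wetness index.

    Each layer holds a wetness index in [0, 1] that decays geometrically on
    dry days and is recharged by rainfall; psi = psi_min * (1 - w)^2 so a
    saturated layer sits near 0 MPa.  With zero rainfall the potentials
    decay monotonically.
    """
    H = len(rainfall)
    w = np.full(3, start_wetness, dtype=float)
    psi = np.empty((H, 3))
    for d in range(H):
        w = w * (1.0 - _DRY_RATE) + _RECHARGE * min(rainfall[d], 20.0) / 20.0
        w = np.clip(w, 0.0, 1.0)
        psi[d] = _PSI_MIN * (1.0 - w) ** 2
    return psi


def generate_weather(
    template: str, horizon_days: int = 45, rng_seed: int | np.random.SeedSequence = 0
) -> WeatherSeries:
    """Generate a daily weather series from a named template.

    Soil temperature is template mean plus AR(1) noise; rainfall is a
    Bernoulli-gamma process; layer potentials follow rainfall through a
    drying/recharge wetness index.  The special template ``"no_stress"`` is
    deterministic: constant 20 deg C, 4 mm rain every day, all layers near
    saturation — no germination or growth limitation of any kind.
    """
    if template == "no_stress":
        H = horizon_days
        return WeatherSeries(
            soil_temp=np.full(H, 20.0),
            rainfall=np.full(H, 4.0),
            psi=np.full((H, 3), -0.01),
        )
    if template not in WEATHER_TEMPLATES:
        raise ConfigError(
            f"unknown weather template {template!r}; "
            f"choose from {sorted(WEATHER_TEMPLATES) + ['no_stress']}"
        )
    tpl = WEATHER_TEMPLATES[template]
    rng = np.random.default_rng(rng_seed)
    H = horizon_days
    noise = np.empty(H)
    eps = rng.normal(0.0, tpl.temp_sd * math.sqrt(1 - tpl.temp_ar1 ** 2), size=H)
    prev = rng.normal(0.0, tpl.temp_sd)
    for d in range(H):
        prev = tpl.temp_ar1 * prev + eps[d]
        noise[d] = prev
    soil_temp = tpl.mean_temp + noise
    events = rng.random(H) < tpl.rain_prob
    amounts = rng.gamma(tpl.rain_shape, tpl.rain_scale, size=H)
    rainfall = np.where(events, amounts, 0.0)
    psi = _potentials_from_rain(rainfall, tpl.start_wetness)
    return WeatherSeries(soil_temp=soil_temp, rainfall=rainfall, psi=psi)


# ---------------------------------------------------------------------------
# Seedbed templates
# ---------------------------------------------------------------------------

#: A coarse conventional-tillage seedbed: many small clods, some large,
#: a fraction lying on the surface.
_COARSE_AGGREGATES = [
    AggregateClass(diameter_cm=2.0, count_per_m2=400.0, surface=False),
    AggregateClass(diameter_cm=4.0, count_per_m2=150.0, surface=False),
    AggregateClass(diameter_cm=3.0, count_per_m2=100.0, surface=True),
]

_SOIL_CRUSTING = {
    "clay": "non_crusting",
    "silty_loam": "highly_crusting",
    "silty_clay_loam": "moderately_crusting",
    "clay_loam": "moderately_crusting",
    "silty_clay": "non_crusting",
}


def seedbed_templates(name: str, n_seeds: int = 1000) -> SeedbedConfig:
    """Seedbed configuration for a named soil type.

    Clay-dominated soils resist surface crusting; silty loam is highly
    crust-prone and the intermediate loams moderately so.  All templates
    share a coarse seedbed structure typical of conventional tillage and a
    sowing depth of 3.0 +/- 0.7 cm.
    """
    if name not in _SOIL_CRUSTING:
        raise ConfigError(f"unknown seedbed template {name!r}; choose from {sorted(_SOIL_CRUSTING)}")
    return SeedbedConfig(
        n_seeds=n_seeds,
        depth_mean=3.0,
        depth_sd=0.7,
        depth_bounds=(1.0, 6.0),
        aggregate_spec=[AggregateClass(a.diameter_cm, a.count_per_m2, a.surface)
                        for a in _COARSE_AGGREGATES],
        soil_crusting_class=_SOIL_CRUSTING[name],
    )
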