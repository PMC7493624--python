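"""Estimation of soybean germination parameters from laboratory time courses.

Seed lots are incubated at a range of constant temperatures (or, at a fixed
temperature, a range of water potentials imposed osmotically) and the
cumulative number of germinated seeds is scored over time.  From such
time courses this module estimates the cardinal germination parameters used
by the emergence simulator:

* the base temperature ``Tb`` below which the germination rate is zero,
  obtained as the x-intercept of the linear regression of germination rate
  (1/time to reach a given percentile) against temperature over the
  sub-optimal range;
* the optimum temperature ``Topt`` at which germination is fastest, from a
  unimodal beta-type temperature-response fit;
* the base water potential ``psi_b`` below which germination stops, as the
  x-intercept of rate against water potential;
* the distribution of thermal time (degree-days above ``Tb``) a seed needs
  to germinate, together with the germinable fraction of the lot.

Cumulative germination courses are summarised by a three-parameter Gompertz
curve ``g(t) = A * exp(-exp(-k*(t - tm)))`` whose closed-form inverse gives
the percentile times.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DegenerateDataError,
    EstimationError,
    FitFailureError,
    InsufficientDataError,
)

#: Germination percentiles used throughout (fractions of sown seeds, in %).
PERCENTILES: tuple[int, ...] = (20, 40, 50, 60, 80, 90)

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# Gompertz curve
# ---------------------------------------------------------------------------

def gompertz(t, A, k, tm):
    """Cumulative Gompertz curve A * exp(-exp(-k*(t - tm)))."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow collapses to exp(-inf) = 0
        return A * np.exp(-np.exp(-k * (t - tm)))


def gompertz_inverse(p, A, k, tm):
    """Time at which the Gompertz curve reaches cumulative fraction ``p``.

    Only defined for 0 < p < A; returns NaN outside that range.
    """
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p / A
        out = np.where(
            (p > 0) & (ratio < 1.0),
            tm - np.log(-np.log(np.clip(ratio, 1e-300, 1 - 1e-16))) / k,
            np.nan,
        )
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GerminationTimeCourse:
    """Replicated cumulative germination counts at one incubation level.

    Parameters
    ----------
    level_type:
        ``"temperature"`` (level in deg C) or ``"water_potential"``
        (level in MPa).
    level_value:
        The incubation temperature or water potential.
    seeds_per_replicate:
        Number of seeds per Petri dish.
    observations:
        One list per replicate of ``(time_h, cumulative_count)`` pairs,
        times in hours since imbibition.
    """

    level_type: str
    level_value: float
    seeds_per_replicate: int
    observations: list[list[tuple[float, int]]]

    def __post_init__(self):
        if self.level_type not in ("temperature", "water_potential"):
            raise ValueError(f"unknown level_type {self.level_type!r}")
        if self.seeds_per_replicate <= 0:
            raise ValueError("seeds_per_replicate must be positive")
        for rep in self.observations:
            times = [t for t, _ in rep]
            counts = [c for _, c in rep]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError("times must be strictly increasing within a replicate")
            if any(c2 < c1 for c1, c2 in zip(counts, counts[1:])):
                raise ValueError("cumulative counts must be non-decreasing")
            if any(c < 0 or c > self.seeds_per_replicate for c in counts):
                raise ValueError("counts must lie in [0, seeds_per_replicate]")

    @property
    def n_replicates(self) -> int:
        return len(self.observations)

    def pooled_points(self) -> tuple[np.ndarray, np.ndarray]:
        """All (time_h, cumulative fraction) points pooled across replicates."""
        t, y = [], []
        for rep in self.observations:
            for time_h, count in rep:
                t.append(time_h)
                y.append(count / self.seeds_per_replicate)
        order = np.argsort(t)
        return np.asarray(t, float)[order], np.asarray(y, float)[order]


@dataclass
class GompertzFit:
    """Fitted cumulative Gompertz curve for one germination course."""

    A: float          # asymptote = final germination fraction
    k: float          # rate parameter, 1/time
    tm: float         # inflection time, same unit as input times
    rss: float        # residual sum of squares of the fit
    n_points: int = 0
    time_unit: str = "h"

    def __call__(self, t):
        return gompertz(t, self.A, self.k, self.tm)

    def inverse(self, p):
        return gompertz_inverse(p, self.A, self.k, self.tm)


@dataclass
class PercentileRates:
    """Germination rates 1/Tp for a set of percentiles at one level.

    ``rates`` maps percentile (e.g. 50) to 1/time-to-reach-that-percentile;
    the time unit follows the underlying fit (hours by default).  Percentiles
    the fitted curve never reaches carry NaN.
    """

    rates: dict[int, float]
    times: dict[int, float]
    level_value: float | None = None

    def rate_array(self, percentiles: Sequence[int]) -> np.ndarray:
        return np.array([self.rates.get(p, np.nan) for p in percentiles])


@dataclass
class ThermalTimeDistribution:
    """Discrete distribution of thermal time to germination (deg C day).

    The distribution is held as probabilities over contiguous classes
    ``[edges[i], edges[i+1])``; sampling draws a class and then a uniform
    value within it, so a zero-width class acts as a point mass.
    """

    edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.edges) != len(self.probs) + 1:
            raise ValueError("need len(edges) == len(probs) + 1")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative class probability")
        total = self.probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")

    @classmethod
    def point_mass(cls, value: float) -> "ThermalTimeDistribution":
        return cls(edges=np.array([value, value]), probs=np.array([1.0]))

    @classmethod
    def from_gompertz(
        cls, A: float, k: float, tm: float,
        class_width: float = 5.0, upper: float = 60.0,
    ) -> "ThermalTimeDistribution":
        """Discretise a Gompertz CDF in thermal time into probability classes."""
        edges = np.arange(0.0, upper + class_width / 2, class_width)
        cdf = gompertz(edges, 1.0, k, tm)  # normalised: A handled separately
        probs = np.diff(cdf)
        probs = probs / probs.sum()
        return cls(edges=edges, probs=probs)

    def quantile(self, q):
        """Inverse CDF by linear interpolation within classes."""
        q = np.asarray(q, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(self.probs)])
        cum[-1] = 1.0
        out = np.interp(q, cum, self.edges)
        return float(out) if out.ndim == 0 else out

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.quantile(rng.random(size))

    @property
    def median(self) -> float:
        return float(self.quantile(0.5))

    def to_dict(self) -> dict:
        return {"edges": self.edges.tolist(), "probs": self.probs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ThermalTimeDistribution":
        return cls(edges=np.asarray(d["edges"]), probs=np.asarray(d["probs"]))


@dataclass
class CultivarGerminationParams:
    """Germination parameters of one cultivar, as used by the simulator."""

    name: str
    Tb: float                                  # base temperature, deg C
    Topt: float                                # optimum temperature, deg C
    psi_b_mean: float                          # mean base water potential, MPa
    germinable_fraction: float
    thermal_time_distribution: ThermalTimeDistribution
    psi_b_by_percentile: dict[int, float] = field(default_factory=dict)
    Tmin_fit: float | None = None
    Tmax_fit: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.germinable_fraction <= 1.0):
            raise ValueError("germinable_fraction must lie in [0, 1]")
        if self.Tb >= self.Topt:
            raise ValueError("require Tb < Topt")
        if self.psi_b_mean > 0 or any(v > 0 for v in self.psi_b_by_percentile.values()):
            raise ValueError("base water potentials must be <= 0 MPa")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "Tb": self.Tb,
            "Topt": self.Topt,
            "Tmin_fit": self.Tmin_fit,
            "Tmax_fit": self.Tmax_fit,
            "psi_b_mean": self.psi_b_mean,
            "psi_b_by_percentile": {str(k): v for k, v in self.psi_b_by_percentile.items()},
            "germinable_fraction": self.germinable_fraction,
            "thermal_time_distribution": self.thermal_time_distribution.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CultivarGerminationParams":
        return cls(
            name=d["name"],
            Tb=d["Tb"],
            Topt=d["Topt"],
            Tmin_fit=d.get("Tmin_fit"),
            Tmax_fit=d.get("Tmax_fit"),
            psi_b_mean=d["psi_b_mean"],
            psi_b_by_percentile={int(k): v for k, v in d.get("psi_b_by_percentile", {}).items()},
            germinable_fraction=d["germinable_fraction"],
            thermal_time_distribution=ThermalTimeDistribution.from_dict(
                d["thermal_time_distribution"]
            ),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CultivarGerminationParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Gompertz fitting
# ---------------------------------------------------------------------------

def fit_gompertz(
    tc: GerminationTimeCourse,
    max_restarts: int = 10,
    restart_seed: int = 0,
) -> GompertzFit:
    """Least-squares Gompertz fit to a pooled germination time course.

    Replicates are pooled by concatenating their (time, fraction) points,
    which for a shared observation schedule is equivalent to fitting the
    replicate-summed counts.  A data-driven initial guess is tried first;
    on non-convergence up to ``max_restarts`` random restarts are drawn from
    data-driven ranges with a fixed seed, so the fit is deterministic.
    """
    t, y = tc.pooled_points()
    if np.all(y == 0):
        raise DegenerateDataError(
            f"no germination observed at level {tc.level_value}"
        )
    if len(np.unique(t)) < 4:
        raise InsufficientDataError("need >= 4 distinct observation times")

    ymax = float(y.max())
    tmax = float(t.max())
    # inflection near the time the course crosses half its plateau
    tm0 = float(t[np.argmin(np.abs(y - ymax / 2))])
    rise = t[y >= 0.8 * ymax]
    start = t[y >= 0.2 * ymax]
    spread = max(float(rise.min() - start.min()), (t[1] - t[0])) if len(rise) else tmax / 4
    k0 = 2.0 / max(spread, 1e-6)

    lower = [1e-6, 1e-6, -0.5 * tmax]
    upper = [1.0, 50.0 / max(spread, 1e-6), 2.0 * tmax]
    inits = [(min(ymax + 0.02, 1.0), k0, tm0)]
    rng = np.random.default_rng(restart_seed)
    for _ in range(max_restarts):
        inits.append((
            float(rng.uniform(max(ymax - 0.1, 0.05), 1.0)),
            float(rng.uniform(0.2 * k0, 5.0 * k0)),
            float(rng.uniform(0.2 * tm0 if tm0 > 0 else 0.0, 1.5 * tm0 + 1.0)),
        ))

    best_rss = None
    for p0 in inits:
        p0 = np.clip(p0, lower, upper)
        try:
            popt, _ = optimize.curve_fit(
                gompertz, t, y, p0=p0, bounds=(lower, upper), maxfev=5000
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        rss = float(np.sum((gompertz(t, *popt) - y) ** 2))
        if math.isfinite(rss):
            return GompertzFit(
                A=float(popt[0]), k=float(popt[1]), tm=float(popt[2]),
                rss=rss, n_points=len(t),
            )
        best_rss = rss if best_rss is None else min(best_rss, rss)
    raise FitFailureError(
        f"Gompertz fit did not converge at level {tc.level_value}", best_rss
    )


def percentile_rates(
    fit: GompertzFit,
    percentiles: Sequence[int] = PERCENTILES,
    level_value: float | None = None,
) -> PercentileRates:
    """Germination rates 1/Tp from a fitted curve's closed-form inverse.

    A percentile the curve never reaches (p/100 >= A), or that is reached at
    a non-positive time, yields NaN for that entry rather than an error.
    """
    rates: dict[int, float] = {}
    times: dict[int, float] = {}
    for p in percentiles:
        tp = fit.inverse(p / 100.0)
        if not math.isfinite(tp) or tp <= 0:
            rates[p] = math.nan
            times[p] = math.nan
        else:
            rates[p] = 1.0 / tp
            times[p] = tp
    return PercentileRates(rates=rates, times=times, level_value=level_value)


# ---------------------------------------------------------------------------
# Cardinal temperature / water potential estimation
# ---------------------------------------------------------------------------

@dataclass
class XInterceptRegression:
    slope: float
    intercept: float
    r2: float
    x_intercept: float
    n: int


@dataclass
class BaseEstimate:
    """Result of an x-intercept estimation (base temperature or potential)."""

    value: float                                # mean x-intercept
    by_percentile: dict[int, XInterceptRegression]
    levels_used: list[float]
    warnings: list[str] = field(default_factory=list)


def _x_intercept_fit(x: np.ndarray, r: np.ndarray) -> XInterceptRegression:
    res = stats.linregress(x, r)
    return XInterceptRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue ** 2),
        x_intercept=float(-res.intercept / res.slope) if res.slope != 0 else math.nan,
        n=len(x),
    )


def estimate_base_temperature(
    rates_by_temperature: Mapping[float, PercentileRates],
    r2_threshold: float = 0.95,
    temperatures: Sequence[float] | None = None,
    percentiles: Sequence[int] = PERCENTILES,
) -> BaseEstimate:
    """Base temperature as the x-intercept of rate-vs-temperature regressions.

    For each germination percentile, ordinary least squares of 1/Tp against
    incubation temperature over the sub-optimal linear range; Tb is the
    unweighted mean of the per-percentile x-intercepts.

    The linear range is, by default, the largest contiguous set of
    temperatures at or below the rate peak for which every usable percentile
    regression reaches R^2 >= ``r2_threshold``; pass ``temperatures`` to
    override the selection with an explicit list.
    """
    temps = np.array(sorted(rates_by_temperature))
    R = np.array([
        rates_by_temperature[T].rate_array(percentiles) for T in temps
    ])  # shape (n_temps, n_percentiles)

    warnings: list[str] = []
    if temperatures is not None:
        window = [T for T in sorted(temperatures) if T in temps]
        if len(window) < 3:
            raise InsufficientDataError("explicit temperature range has < 3 usable levels")
    else:
        mean_rate = np.nanmean(np.where(np.isnan(R), np.nan, R), axis=1)
        usable = ~np.all(np.isnan(R), axis=1)
        if usable.sum() < 3:
            raise InsufficientDataError("fewer than 3 temperatures with defined rates")
        i_peak = int(np.nanargmax(mean_rate))
        cand = temps[: i_peak + 1]
        if len(cand) < 3:
            # rates peak at (or near) the coldest level: no sub-optimal range
            # exists, so regress over everything and let the slope check
            # decide whether there is a thermal response at all
            cand = temps
        window = _select_linear_window(cand, temps, R, percentiles, r2_threshold, warnings)

    idx = [int(np.where(temps == T)[0][0]) for T in window]
    by_percentile: dict[int, XInterceptRegression] = {}
    for j, p in enumerate(percentiles):
        r = R[idx, j]
        ok = np.isfinite(r)
        if ok.sum() < 3:
            continue
        fitp = _x_intercept_fit(np.asarray(window, float)[ok], r[ok])
        if fitp.slope <= 0:
            raise EstimationError(
                f"non-positive slope for percentile {p}: no thermal response"
            )
        by_percentile[p] = fitp
    if not by_percentile:
        raise InsufficientDataError("no percentile has >= 3 defined rates in the range")
    value = float(np.mean([f.x_intercept for f in by_percentile.values()]))
    return BaseEstimate(
        value=value, by_percentile=by_percentile,
        levels_used=[float(T) for T in window], warnings=warnings,
    )


def _select_linear_window(cand, temps, R, percentiles, r2_threshold, warnings):
    """Largest contiguous sub-peak window where all percentile fits are linear."""
    best_fallback, best_fallback_score = None, -np.inf
    for size in range(len(cand), 2, -1):
        candidates = []
        for start in range(0, len(cand) - size + 1):
            window = list(cand[start:start + size])
            idx = [int(np.where(temps == T)[0][0]) for T in window]
            r2s = []
            for j, _p in enumerate(percentiles):
                r = R[idx, j]
                ok = np.isfinite(r)
                if ok.sum() < 3:
                    continue
                res = stats.linregress(np.asarray(window, float)[ok], r[ok])
                r2s.append(res.rvalue ** 2)
            if not r2s:
                continue
            score = float(np.mean(r2s))
            if score > best_fallback_score:
                best_fallback, best_fallback_score = window, score
            if min(r2s) >= r2_threshold:
                candidates.append((score, window))
        if candidates:
            return max(candidates)[1]
    warnings.append(
        f"no contiguous window met R^2 >= {r2_threshold}; "
        f"using best available (mean R^2 = {best_fallback_score:.3f})"
    )
    if best_fallback is None:
        raise InsufficientDataError("no usable temperature window")
    return best_fallback


def estimate_base_water_potential(
    rates_by_potential: Mapping[float, PercentileRates],
    percentiles: Sequence[int] = PERCENTILES,
) -> BaseEstimate:
    """Base water potential as the x-intercept of rate-vs-psi regressions.

    All supplied water-potential levels (measured at a single temperature)
    enter each per-percentile regression; psi_b(p) is the x-intercept and the
    summary value is their unweighted mean.  Fast-germinating percentiles are
    expected to show more negative psi_b than slow ones.
    """
    levels = np.array(sorted(rates_by_potential))
    if len(levels) < 3:
        raise InsufficientDataError("need >= 3 water-potential levels")
    R = np.array([rates_by_potential[v].rate_array(percentiles) for v in levels])
    by_percentile: dict[int, XInterceptRegression] = {}
    for j, p in enumerate(percentiles):
        r = R[:, j]
        ok = np.isfinite(r)
        if ok.sum() < 3:
            continue
        fitp = _x_intercept_fit(levels[ok], r[ok])
        if fitp.slope <= 0:
            raise EstimationError(
                f"non-positive slope for percentile {p}: no water-potential response"
            )
        by_percentile[p] = fitp
    if not by_percentile:
        raise InsufficientDataError("no percentile has >= 3 defined rates")
    value = float(np.mean([f.x_intercept for f in by_percentile.values()]))
    return BaseEstimate(
        value=value, by_percentile=by_percentile,
        levels_used=[float(v) for v in levels],
    )


# ---------------------------------------------------------------------------
# Optimum temperature (beta-type temperature response)
# ---------------------------------------------------------------------------

def beta_temperature_response(T, rmax, Tmin, Topt, Tmax):
    """Unimodal beta-type response, zero outside (Tmin, Tmax), peak at Topt."""
    T = np.asarray(T, dtype=float)
    if not (Tmin < Topt < Tmax):
        return np.full_like(T, 1e6)
    expo = (Topt - Tmin) / (Tmax - Topt)
    with np.errstate(invalid="ignore"):
        r = (
            rmax
            * ((Tmax - T) / (Tmax - Topt))
            * np.power(np.clip((T - Tmin) / (Topt - Tmin), 0.0, None), expo)
        )
    return np.where((T > Tmin) & (T < Tmax), r, 0.0)


@dataclass
class OptimumTemperatureEstimate:
    Topt: float
    Tmin_fit: float
    Tmax_fit: float
    rmax: float
    boundary_warning: bool = False


def estimate_optimum_temperature(
    rates_by_temperature: Mapping[float, PercentileRates],
    percentile: int = 50,
    max_restarts: int = 10,
    restart_seed: int = 0,
) -> OptimumTemperatureEstimate:
    """Optimum germination temperature from a beta-type response fit.

    Fits r(T) = rmax * ((Tmax-T)/(Tmax-Topt)) * ((T-Tmin)/(Topt-Tmin))**e
    with e = (Topt-Tmin)/(Tmax-Topt) to the rate of the given percentile
    (default: median germination, 1/T50); Topt is a fit parameter and the
    curve's argmax.  If the fitted optimum falls outside the observed
    temperature range, the data argmax is returned with a boundary warning.
    """
    temps = np.array(sorted(rates_by_temperature))
    r = np.array([rates_by_temperature[T].rates.get(percentile, np.nan) for T in temps])
    ok = np.isfinite(r)
    temps, r = temps[ok], r[ok]
    if len(temps) < 5:
        raise InsufficientDataError("need rates at >= 5 temperatures")

    T_at_max = float(temps[np.argmax(r)])
    p0 = (float(r.max()), float(temps.min() - 2.0), T_at_max, float(temps.max() + 2.0))
    lower = [1e-9, -15.0, temps.min() - 5.0, temps.min()]
    upper = [10.0 * r.max(), temps.min() + 1e-6 + 40.0, temps.max() + 5.0, 80.0]
    rng = np.random.default_rng(restart_seed)
    attempts = [p0]
    for _ in range(max_restarts):
        attempts.append((
            float(r.max() * rng.uniform(0.8, 1.5)),
            float(rng.uniform(-10.0, temps.min())),
            float(rng.uniform(temps.min(), temps.max())),
            float(rng.uniform(T_at_max + 1.0, 70.0)),
        ))
    best = None
    for guess in attempts:
        guess = np.clip(guess, lower, upper)
        try:
            popt, _ = optimize.curve_fit(
                beta_temperature_response, temps, r, p0=guess,
                bounds=(lower, upper), maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((beta_temperature_response(temps, *popt) - r) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise FitFailureError("temperature-response fit did not converge")
    _, (rmax, Tmin, Topt, Tmax) = best
    boundary = not (temps.min() < Topt < temps.max())
    if boundary:
        Topt = T_at_max
    return OptimumTemperatureEstimate(
        Topt=float(Topt), Tmin_fit=float(Tmin), Tmax_fit=float(Tmax),
        rmax=float(rmax), boundary_warning=boundary,
    )


# ---------------------------------------------------------------------------
# Thermal-time distribution
# ---------------------------------------------------------------------------

@dataclass
class ThermalTimeDerivation:
    distribution: ThermalTimeDistribution
    germinable_fraction: float
    pooled_fit: GompertzFit
    collapse_rms: float
    warnings: list[str] = field(default_factory=list)


def derive_thermal_time_distribution(
    courses: Iterable[GerminationTimeCourse],
    Tb: float,
    class_width: float = 5.0,
    upper: float = 60.0,
    collapse_tol: float = 0.05,
) -> ThermalTimeDerivation:
    """Pool courses on a thermal-time axis and discretise the fitted CDF.

    Each course's observation times are converted to thermal time
    ``(T - Tb) * t`` in deg C day (constant incubator temperature per
    course); the pooled points are fitted with a single Gompertz curve whose
    normalised density is discretised into classes of ``class_width`` deg C
    day over [0, upper].  The pooled asymptote is the germinable fraction.

    A diagnostic checks that the individual courses collapse onto one curve
    in thermal time: the RMS deviation between per-level curves interpolated
    on a common grid is reported, with a warning above ``collapse_tol``.
    """
    courses = list(courses)
    if not courses:
        raise InsufficientDataError("no courses supplied")
    pooled_t, pooled_y, per_level = [], [], []
    for tc in courses:
        if tc.level_type != "temperature":
            raise ValueError("thermal-time pooling needs temperature courses")
        if tc.level_value <= Tb:
            continue
        t, y = tc.pooled_points()
        tt = (tc.level_value - Tb) * t / 24.0  # hours -> days above base
        pooled_t.append(tt)
        pooled_y.append(y)
        per_level.append((tt, y))
    if not pooled_t:
        raise InsufficientDataError("no courses above the base temperature")
    tt = np.concatenate(pooled_t)
    yy = np.concatenate(pooled_y)
    order = np.argsort(tt)
    fit = _fit_gompertz_points(tt[order], yy[order])
    fit.time_unit = "Cd"

    # collapse diagnostic: RMS between per-level curves on a shared grid
    collapse_rms = 0.0
    if len(per_level) > 1:
        lo = max(t.min() for t, _ in per_level)
        hi = min(t.max() for t, _ in per_level)
        if hi > lo:
            grid = np.linspace(lo, hi, 25)
            interped = np.array([
                np.interp(grid, t, y) for t, y in per_level
            ])
            collapse_rms = float(
                np.sqrt(np.mean((interped - interped.mean(axis=0)) ** 2))
            )
    warnings = []
    if collapse_rms > collapse_tol:
        warnings.append(
            f"thermal-time curves do not collapse (RMS {collapse_rms:.3f} > {collapse_tol})"
        )
    dist = ThermalTimeDistribution.from_gompertz(
        fit.A, fit.k, fit.tm, class_width=class_width, upper=upper
    )
    return ThermalTimeDerivation(
        distribution=dist,
        germinable_fraction=float(np.clip(fit.A, 0.0, 1.0)),
        pooled_fit=fit,
        collapse_rms=collapse_rms,
        warnings=warnings,
    )


def _fit_gompertz_points(t: np.ndarray, y: np.ndarray) -> GompertzFit:
    """Gompertz fit on raw (time, fraction) points (internal helper)."""
    if np.all(y == 0):
        raise DegenerateDataError("all-zero fractions")
    ymax = float(y.max())
    tm0 = float(t[np.argmin(np.abs(y - ymax / 2))])
    spread = max((t.max() - t.min()) / 6.0, 1e-6)
    p0 = (min(ymax + 0.02, 1.0), 2.0 / spread, tm0)
    lower = [1e-6, 1e-6, -0.5 * float(t.max())]
    upper = [1.0, 200.0 / spread, 2.0 * float(t.max())]
    try:
        popt, _ = optimize.curve_fit(
            gompertz, t, y, p0=np.clip(p0, lower, upper),
            bounds=(lower, upper), maxfev=5000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"pooled Gompertz fit failed: {exc}") from exc
    rss = float(np.sum((gompertz(t, *popt) - y) ** 2))
    return GompertzFit(A=float(popt[0]), k=float(popt[1]), tm=float(popt[2]),
                       rss=rss, n_points=len(t))


# ---------------------------------------------------------------------------
# CSV I/O (long format)
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "cultivar", "level_type", "level_value", "replicate",
    "time_h", "cum_germinated", "seeds_total",
]


def read_time_courses(path) -> dict[str, list[GerminationTimeCourse]]:
    """Read lab time courses from a long-format CSV, grouped by cultivar."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"time-course CSV missing columns: {sorted(missing)}")
    out: dict[str, list[GerminationTimeCourse]] = {}
    for (cultivar, level_type, level_value), grp in df.groupby(
        ["cultivar", "level_type", "level_value"], sort=True
    ):
        seeds = int(grp["seeds_total"].iloc[0])
        observations = []
        for _, rep in grp.groupby("replicate", sort=True):
            rep = rep.sort_values("time_h")
            observations.append(
                list(zip(rep["time_h"].astype(float), rep["cum_germinated"].astype(int)))
            )
        out.setdefault(str(cultivar), []).append(GerminationTimeCourse(
            level_type=str(level_type), level_value=float(level_value),
            seeds_per_replicate=seeds, observations=observations,
        ))
    return out


def write_time_courses(path, courses_by_cultivar: Mapping[str, list[GerminationTimeCourse]]):
    """Write time courses to the long CSV dialect read_time_courses expects."""
    rows = []
    for cultivar, courses in courses_by_cultivar.items():
        for tc in courses:
            for rep_i, rep in enumerate(tc.observations, start=1):
                for time_h, count in rep:
                    rows.append((cultivar, tc.level_type, tc.level_value,
                                 rep_i, time_h, count, tc.seeds_per_replicate))
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
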