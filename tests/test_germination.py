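"""Tests for laboratory germination-parameter estimation."""

import math

import numpy as np
import pytest

import soyemerge as se
from soyemerge.errors import DegenerateDataError, EstimationError
from soyemerge.germination import (
    PERCENTILES,
    GompertzFit,
    PercentileRates,
    ThermalTimeDistribution,
    beta_temperature_response,
    gompertz,
    gompertz_inverse,
)


def make_course(A, k, tm, times, seeds=100, level=20.0):
    """A noiseless time course sampled exactly from a Gompertz curve."""
    counts = np.round(gompertz(times, A, k, tm) * seeds).astype(int)
    return se.GerminationTimeCourse(
        level_type="temperature", level_value=level, seeds_per_replicate=seeds,
        observations=[list(zip(times, counts))],
    )


class TestGompertzFit:
    def test_exact_curve_recovery(self):
        times = np.linspace(5, 120, 40)
        seeds = 10**6  # rounding noise negligible
        tc = make_course(0.99, 0.1, 30.0, times, seeds=seeds)
        fit = se.fit_gompertz(tc)
        assert fit.A == pytest.approx(0.99, rel=1e-4)
        assert fit.k == pytest.approx(0.1, rel=1e-3)
        assert fit.tm == pytest.approx(30.0, rel=1e-3)

    def test_plateau_asymptote_recovered(self):
        # a course plateauing at 99/100 seeds yields A near 0.99
        times = np.linspace(4, 150, 50)
        tc = make_course(0.99, 0.08, 40.0, times, seeds=100)
        fit = se.fit_gompertz(tc)
        assert fit.A == pytest.approx(0.99, abs=0.01)

    def test_binomial_noise_recovery(self):
        # 4 x 25 seeds from a known curve; median of fitted A near truth
        rng = np.random.default_rng(42)
        times = np.arange(8, 160, 8.0)
        A_hats = []
        for _ in range(200):
            probs = gompertz(times, 0.97, 0.08, 40.0)
            observations = []
            for _rep in range(4):
                u = rng.random(25)
                # each seed germinates at the time its quantile is crossed
                counts = (u[:, None] < probs[None, :] / 1.0).sum(axis=0)
                observations.append(list(zip(times, counts)))
            tc = se.GerminationTimeCourse(
                level_type="temperature", level_value=20.0,
                seeds_per_replicate=25, observations=observations,
            )
            A_hats.append(se.fit_gompertz(tc).A)
        assert abs(np.median(A_hats) - 0.97) < 0.02

    def test_all_zero_counts_raises(self):
        tc = se.GerminationTimeCourse(
            level_type="temperature", level_value=3.0, seeds_per_replicate=25,
            observations=[[(8.0, 0), (16.0, 0), (24.0, 0), (32.0, 0)]],
        )
        with pytest.raises(DegenerateDataError):
            se.fit_gompertz(tc)

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            se.GerminationTimeCourse(
                level_type="temperature", level_value=20.0, seeds_per_replicate=25,
                observations=[[(8.0, 5), (16.0, 3)]],  # decreasing counts
            )


class TestPercentileRates:
    def test_t50_closed_form(self):
        fit = GompertzFit(A=1.0, k=0.1, tm=30.0, rss=0.0)
        pr = se.percentile_rates(fit)
        t50 = 30.0 - math.log(math.log(2.0)) / 0.1
        assert pr.times[50] == pytest.approx(t50)
        assert pr.times[50] == pytest.approx(33.665, abs=1e-3)
        assert pr.rates[50] == pytest.approx(1.0 / t50)

    def test_unreachable_percentile_is_nan(self):
        fit = GompertzFit(A=0.85, k=0.1, tm=30.0, rss=0.0)
        pr = se.percentile_rates(fit)
        assert math.isnan(pr.rates[90])
        assert not math.isnan(pr.rates[80])

    def test_inverse_forward_round_trip(self):
        fit = GompertzFit(A=0.95, k=0.07, tm=42.0, rss=0.0)
        for p in (0.1, 0.3, 0.5, 0.8, 0.94):
            assert gompertz(gompertz_inverse(p, 0.95, 0.07, 42.0), 0.95, 0.07, 42.0) \
                == pytest.approx(p, abs=1e-9)

    def test_times_increase_with_percentile(self):
        fit = GompertzFit(A=0.97, k=0.05, tm=50.0, rss=0.0)
        times = [se.percentile_rates(fit).times[p] for p in PERCENTILES]
        assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))

    def test_time_scaling_scales_all_rates(self):
        # compressing the curve's time axis by c (k -> c*k, tm -> tm/c)
        # multiplies every percentile rate by c
        base = se.percentile_rates(GompertzFit(A=1.0, k=0.1, tm=30.0, rss=0.0))
        for c in (0.5, 2.0, 4.0):
            fast = se.percentile_rates(
                GompertzFit(A=1.0, k=0.1 * c, tm=30.0 / c, rss=0.0))
            for p in PERCENTILES:
                assert fast.rates[p] == pytest.approx(c * base.rates[p])

    def test_rates_increase_with_k_above_inflection(self):
        # at fixed tm a larger k speeds percentiles beyond the inflection
        # point (p > 1/e); below it the effect reverses, so only p >= 40
        # carries the monotonicity
        for p in (40, 50, 60, 80, 90):
            rates = [
                se.percentile_rates(GompertzFit(A=1.0, k=k, tm=30.0, rss=0.0)).rates[p]
                for k in (0.05, 0.1, 0.2, 0.4)
            ]
            assert all(r2 > r1 for r1, r2 in zip(rates, rates[1:]))


def linear_rates(levels, slope, x0):
    """PercentileRates that are exactly linear in the level for every percentile."""
    out = {}
    for lv in levels:
        r = slope * (lv - x0)
        out[lv] = PercentileRates(
            rates={p: r for p in PERCENTILES},
            times={p: 1.0 / r if r > 0 else math.nan for p in PERCENTILES},
            level_value=lv,
        )
    return out


class TestBaseTemperature:
    def test_exact_x_intercept(self):
        rates = linear_rates([10, 15, 20, 25], 0.05, 5.0)
        est = se.estimate_base_temperature(rates)
        assert est.value == pytest.approx(5.0, abs=1e-9)
        assert all(f.r2 > 0.999999 for f in est.by_percentile.values())

    def test_explicit_range_override(self):
        rates = linear_rates([10, 15, 20, 25], 0.05, 5.0)
        est = se.estimate_base_temperature(rates, temperatures=[10, 15, 20])
        assert est.levels_used == [10.0, 15.0, 20.0]
        assert est.value == pytest.approx(5.0, abs=1e-9)

    def test_negative_slope_raises(self):
        rates = linear_rates([10, 15, 20, 25], -0.01, 40.0)
        with pytest.raises(EstimationError):
            se.estimate_base_temperature(rates)

    def test_supra_optimal_levels_excluded(self):
        # rates rise to a peak at 30 then fall: the falling branch must not
        # corrupt the x-intercept
        rates = linear_rates([10, 15, 20, 25, 30], 0.05, 5.0)
        rates[35.0] = PercentileRates(
            rates={p: 0.3 for p in PERCENTILES}, times={}, level_value=35.0)
        rates[40.0] = PercentileRates(
            rates={p: 0.05 for p in PERCENTILES}, times={}, level_value=40.0)
        est = se.estimate_base_temperature(rates)
        assert est.value == pytest.approx(5.0, abs=1e-6)
        assert max(est.levels_used) <= 30.0


class TestBaseWaterPotential:
    def test_exact_x_intercept(self):
        rates = linear_rates([-0.5, -0.25, -0.1, 0.0], 0.2, -0.6)
        est = se.estimate_base_water_potential(rates)
        assert est.value == pytest.approx(-0.6, abs=1e-9)

    def test_percentile_spread_reported(self):
        # different x-intercepts per percentile are all reported
        out = {}
        for lv in (-0.5, -0.25, -0.1, 0.0):
            out[lv] = PercentileRates(
                rates={p: 0.2 * (lv - (-0.75 + 0.25 * p / 100.0)) for p in PERCENTILES},
                times={}, level_value=lv,
            )
        est = se.estimate_base_water_potential(out)
        xs = [f.x_intercept for f in est.by_percentile.values()]
        assert min(xs) == pytest.approx(-0.70, abs=1e-6)   # p=20
        assert max(xs) == pytest.approx(-0.525, abs=1e-6)  # p=90


class TestOptimumTemperature:
    def test_symmetric_rates_peak_at_30(self):
        rbt = {}
        for T in (15, 20, 25, 30, 35, 40, 45):
            r = max(0.0, 0.05 * (1 - ((T - 30) / 15) ** 2))
            rbt[T] = PercentileRates(
                rates={50: r if r > 0 else math.nan}, times={}, level_value=T)
        est = se.estimate_optimum_temperature(rbt)
        assert est.Topt == pytest.approx(30.0, abs=1.0)

    def test_beta_parameter_recovery(self):
        rng = np.random.default_rng(0)
        rbt = {}
        for T in (3, 6.5, 10, 15, 20, 25, 30, 35, 37.5, 40):
            r = float(beta_temperature_response(np.array([T]), 0.05, 3.0, 29.0, 42.0)[0])
            r *= 1 + rng.normal(0, 0.03)
            rbt[T] = PercentileRates(
                rates={50: r if r > 0 else math.nan}, times={}, level_value=T)
        est = se.estimate_optimum_temperature(rbt)
        assert est.Topt == pytest.approx(29.0, abs=1.0)
        assert not est.boundary_warning


class TestThermalTimeDistribution:
    def test_probabilities_sum_to_one(self, ecudor):
        assert ecudor.thermal_time_distribution.probs.sum() == pytest.approx(1.0)

    def test_quantile_is_inverse_of_sampling(self):
        dist = ThermalTimeDistribution(
            edges=np.array([0.0, 10.0, 20.0, 30.0]),
            probs=np.array([0.2, 0.5, 0.3]),
        )
        assert dist.quantile(0.2) == pytest.approx(10.0)
        assert dist.quantile(0.7) == pytest.approx(20.0)
        assert dist.quantile(0.45) == pytest.approx(15.0)

    def test_derivation_round_trip(self, ecudor):
        # courses generated at 15/20/25 C from one thermal-time law collapse
        # and reproduce the generating distribution
        courses = se.generate_time_courses(
            ecudor, temperatures=(15.0, 20.0, 25.0), n_seeds=100, rng_seed=7)
        der = se.derive_thermal_time_distribution(courses, Tb=ecudor.Tb)
        assert not der.warnings
        assert der.collapse_rms < 0.05
        assert der.germinable_fraction == pytest.approx(0.97, abs=0.03)
        assert abs(der.distribution.median - 18.0) < 3.0
        # nearly all mass below 40 deg C day
        below_40 = der.distribution.probs[der.distribution.edges[:-1] < 40.0].sum()
        assert below_40 > 0.98

    def test_class_probs_match_empirical_histogram(self, ecudor):
        # total-variation distance between the derived classes and a direct
        # histogram of per-seed germination thermal times
        rng = np.random.default_rng(3)
        draws = ecudor.thermal_time_distribution.sample(rng, 200_000)
        edges = ecudor.thermal_time_distribution.edges
        hist, _ = np.histogram(draws, bins=edges)
        emp = hist / hist.sum()
        tv = 0.5 * np.abs(emp - ecudor.thermal_time_distribution.probs).sum()
        assert tv < 0.05


class TestCsvRoundTrip:
    def test_write_then_read(self, tmp_path, ecudor):
        courses = se.generate_time_courses(
            ecudor, temperatures=(15.0, 20.0), potentials=(-0.1,), rng_seed=0)
        path = tmp_path / "lab.csv"
        se.write_time_courses(path, {"Ecudor": courses})
        back = se.read_time_courses(path)["Ecudor"]
        assert len(back) == len(courses)
        by_level = {(c.level_type, c.level_value): c for c in back}
        for orig in courses:
            got = by_level[(orig.level_type, orig.level_value)]
            assert got.seeds_per_replicate == orig.seeds_per_replicate
            assert got.observations == [
                [(float(t), int(c)) for t, c in rep] for rep in orig.observations
            ]
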