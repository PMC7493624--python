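"""Daily-time-step stochastic simulation of germination and emergence.

Every sown seed is followed individually.  A seed is intrinsically
non-germinable with probability ``1 - germinable_fraction``; otherwise it
draws a thermal-time requirement (deg C day) from the cultivar's
distribution and accrues hydrothermal time day by day: ``max(0, T_d - Tb)``
on days when the water potential of the seed's soil layer exceeds the base
water potential, nothing otherwise.  Germination occurs the first day the
accrual meets the requirement; seeds not germinated within a 30-day window
never germinate.

After germination the seedling can die of water stress: if on either of the
two days following germination the water potential of the layer the radicle
has reached is below the base water potential, the seedling dies the next
day.  Otherwise the hypocotyl elongates in thermal time above the growth
base temperature, ``L(TT) = Lmax * (1 - exp(-r * TT))``, along a path equal
to the sowing depth plus a detour per circumvented buried aggregate.  Each
encountered buried aggregate blocks the shoot permanently with a
class-specific probability; encounters are drawn Poisson with mean
proportional to the class's areal density, cross-sectional area and the
seed's depth fraction of the tilled layer.  On reaching the surface a
surface-lying aggregate may block once more; a present crust lets the shoot
through on wet-crust days only — a shoot arriving under a dry crust waits up
to ``crust_wait_days`` for a wet day, after which it is blocked for good.

High-temperature injury, waterlogging and biotic stresses are outside the
model's scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, InputError
from .germination import CultivarGerminationParams
from .seedbed import (
    CRUST_ABSENT,
    CRUST_WET,
    SEEDBED_DEPTH_CM,
    Seedbed,
    WeatherSeries,
    layer_index,
    update_crust,
)

#: Per-seed fates: emergence or one of four causes of non-emergence.
CAUSES: tuple[str, ...] = (
    "emerged",
    "non_germination",
    "post_germination_water_stress",
    "blocked_aggregate",
    "blocked_crust",
)

#: Fallback fate for seeds still under way when the horizon ends; kept out of
#: CAUSES because a sufficiently long horizon never produces it.
UNRESOLVED = "unresolved_horizon"

GERMINATION_WINDOW_DAYS = 30


@dataclass
class ElongationParams:
    """Seedling growth parameters (hypocotyl and radicle).

    ``p_block`` maps ``(diameter_cm, surface)`` of an aggregate class to the
    probability that one encountered aggregate of that class blocks the
    shoot permanently; classes not listed fall back to ``default_p_block``.
    ``pathway_detour_cm`` is the extra path length added for every buried
    aggregate the shoot circumvents.
    """

    shoot_Lmax_cm: float = 8.0        # maximum hypocotyl length
    shoot_rate: float = 0.02          # per deg C day
    radicle_rate_cm_per_Cd: float = 0.08
    Tb_growth: float = 4.0            # base temperature for elongation, deg C
    p_block: dict[tuple[float, bool], float] = field(default_factory=dict)
    default_p_block: float = 0.1
    pathway_detour_cm: float = 0.5
    shoot_diameter_cm: float = 0.5    # effective width for aggregate encounters

    def __post_init__(self):
        if self.shoot_Lmax_cm <= 0 or self.shoot_rate <= 0:
            raise ConfigError("elongation parameters must be positive")
        for v in list(self.p_block.values()) + [self.default_p_block]:
            if not (0.0 <= v <= 1.0):
                raise ConfigError("blocking probabilities must lie in [0, 1]")

    def block_probability(self, diameter_cm: float, surface: bool) -> float:
        return self.p_block.get((diameter_cm, surface), self.default_p_block)

    def shoot_length(self, tt: float) -> float:
        return self.shoot_Lmax_cm * (1.0 - math.exp(-self.shoot_rate * tt))

    def thermal_time_to_length(self, length_cm: float) -> float:
        """Inverse of the elongation law; inf if the length is unreachable."""
        frac = length_cm / self.shoot_Lmax_cm
        if frac >= 1.0:
            return math.inf
        return -math.log(1.0 - frac) / self.shoot_rate

    def to_dict(self) -> dict:
        return {
            "shoot_Lmax_cm": self.shoot_Lmax_cm,
            "shoot_rate": self.shoot_rate,
            "radicle_rate_cm_per_Cd": self.radicle_rate_cm_per_Cd,
            "Tb_growth": self.Tb_growth,
            "p_block": [
                {"diameter_cm": d, "surface": s, "p": p}
                for (d, s), p in self.p_block.items()
            ],
            "default_p_block": self.default_p_block,
            "pathway_detour_cm": self.pathway_detour_cm,
            "shoot_diameter_cm": self.shoot_diameter_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElongationParams":
        d = dict(d)
        d["p_block"] = {
            (e["diameter_cm"], bool(e["surface"])): e["p"]
            for e in d.get("p_block", [])
        }
        return cls(**d)


@dataclass
class SeedFate:
    """Per-seed ledger entry: where it was sown and how it ended."""

    seed_id: int
    depth_cm: float
    germination_day: int | None
    emergence_day: int | None
    cause: str

    def __post_init__(self):
        if (self.cause == "emerged") != (self.emergence_day is not None):
            raise ValueError("cause 'emerged' iff emergence_day is set")
        if self.emergence_day is not None and self.germination_day is not None:
            if self.emergence_day < self.germination_day + 1:
                raise ValueError("emergence must be at least one day after germination")


@dataclass
class SimulationResult:
    daily_emerged: np.ndarray          # cumulative emerged count, days 1..H
    final_emergence_rate: float        # % of sown seeds
    cause_partition: dict[str, float]  # % per cause, sums to 100
    fates: list[SeedFate]
    rng_seed: object


def cause_partition(fates: Sequence[SeedFate]) -> dict[str, float]:
    """Percentage of sown seeds per fate category (sums to 100)."""
    if not fates:
        raise InputError("empty fate list")
    n = len(fates)
    counts = {c: 0 for c in CAUSES}
    for f in fates:
        counts[f.cause] = counts.get(f.cause, 0) + 1
    return {c: 100.0 * k / n for c, k in counts.items()}


def _encounter_lambda(seedbed: Seedbed, elong: ElongationParams, depth_cm: float) -> list[tuple[float, float]]:
    """Poisson means and block probabilities for buried-aggregate encounters.

    The expected number of buried aggregates of a class intersecting the
    shoot's upward path is areal density x effective cross-section
    (aggregate diameter plus shoot diameter) x the fraction of the tilled
    layer the path crosses.
    """
    out = []
    for ac in seedbed.aggregate_classes:
        if ac.surface:
            continue
        cross_m2 = math.pi / 4.0 * ((ac.diameter_cm + elong.shoot_diameter_cm) / 100.0) ** 2
        lam = ac.count_per_m2 * cross_m2 * min(depth_cm / SEEDBED_DEPTH_CM, 1.0)
        out.append((lam, elong.block_probability(ac.diameter_cm, False)))
    return out


def _surface_encounter_probability(seedbed: Seedbed, elong: ElongationParams) -> list[tuple[float, float]]:
    out = []
    for ac in seedbed.aggregate_classes:
        if not ac.surface:
            continue
        cross_m2 = math.pi / 4.0 * ((ac.diameter_cm + elong.shoot_diameter_cm) / 100.0) ** 2
        p_enc = min(ac.count_per_m2 * cross_m2, 1.0)
        out.append((p_enc, elong.block_probability(ac.diameter_cm, True)))
    return out


def run_simulation(
    seedbed: Seedbed,
    weather: WeatherSeries,
    germ: CultivarGerminationParams,
    elong: ElongationParams,
    horizon_days: int | None = None,
    rng_seed: int | np.random.SeedSequence = 0,
    germination_window_days: int = GERMINATION_WINDOW_DAYS,
    crust_wait_days: int = 7,
) -> SimulationResult:
    """Simulate every seed of a seedbed through one weather series.

    Daily order of events: hydrothermal accrual, germination check,
    post-germination water-stress check, shoot growth, obstacle checks.
    All randomness flows from ``rng_seed`` through one substream per seed
    (indexed by seed id), so results are reproducible and per-seed draws do
    not shift when other seeds' fates change.
    """
    H = weather.n_days if horizon_days is None else min(horizon_days, weather.n_days)
    if horizon_days is not None and horizon_days > weather.n_days:
        raise InputError("weather series shorter than the requested horizon")
    if H < germination_window_days:
        raise ConfigError(
            f"horizon must cover the {germination_window_days}-day germination window"
        )
    if seedbed.crust_state is None:
        update_crust(seedbed, weather)
    crust = seedbed.crust_state[:H]

    if float(np.max(seedbed.seed_depths)) >= elong.shoot_Lmax_cm:
        raise ConfigError("maximum hypocotyl length must exceed the deepest sowing depth")

    T = weather.soil_temp[:H]
    psi = weather.psi[:H]
    # hydrothermal accrual per layer: degrees above Tb on days with psi > psi_b
    supra = np.clip(T - germ.Tb, 0.0, None)
    acc = np.cumsum(
        supra[:, None] * (psi > germ.psi_b_mean), axis=0
    )  # shape (H, 3): cumulative accrual through day d for a seed in layer l
    G = np.cumsum(np.clip(T - elong.Tb_growth, 0.0, None))  # growth deg C day

    base_ss = (
        rng_seed if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    seed_streams = base_ss.spawn(seedbed.n_seeds)

    window = min(germination_window_days, H)
    fates: list[SeedFate] = []
    for i, depth in enumerate(seedbed.seed_depths):
        rng = np.random.default_rng(seed_streams[i])
        germinable = rng.random() < germ.germinable_fraction
        req = float(germ.thermal_time_distribution.quantile(rng.random()))
        # draw aggregate encounters up front; the daily trajectory is
        # deterministic once the per-seed draws are fixed
        n_enc_blocked = 0
        n_enc_passed = 0
        for lam, p_block in _encounter_lambda(seedbed, elong, depth):
            n = int(rng.poisson(lam))
            if n:
                blocked = int(np.sum(rng.random(n) < p_block))
                n_enc_blocked += blocked
                n_enc_passed += n - blocked
        surface_blocked = False
        for p_enc, p_block in _surface_encounter_probability(seedbed, elong):
            if rng.random() < p_enc and rng.random() < p_block:
                surface_blocked = True

        if not germinable:
            fates.append(SeedFate(i, float(depth), None, None, "non_germination"))
            continue

        lyr = layer_index(depth)
        g = int(np.searchsorted(acc[:window, lyr], req - 1e-12, side="left")) + 1
        if g > window or acc[min(g, H) - 1, lyr] < req - 1e-12:
            fates.append(SeedFate(i, float(depth), None, None, "non_germination"))
            continue

        # tentative emergence day from the elongation law
        path = depth + elong.pathway_detour_cm * n_enc_passed
        tt_req = elong.thermal_time_to_length(path)
        if math.isinf(tt_req):
            # detours pushed the path beyond the hypocotyl's reach
            fates.append(SeedFate(i, float(depth), g, None, "blocked_aggregate"))
            continue
        j = int(np.searchsorted(G, G[g - 1] + tt_req - 1e-12, side="left"))
        e = j + 1  # candidate surface-arrival day (>= g + 1 since tt_req > 0)

        # water stress in the two days following germination
        stress_day = None
        for d in (g + 1, g + 2):
            if d > H:
                break
            tt_growth = G[d - 1] - G[g - 1]
            radicle_depth = depth + elong.radicle_rate_cm_per_Cd * tt_growth
            if psi[d - 1, layer_index(radicle_depth)] < germ.psi_b_mean:
                stress_day = d
                break
        if stress_day is not None and stress_day <= min(e, H):
            fates.append(SeedFate(i, float(depth), g,
                                  None, "post_germination_water_stress"))
            continue

        if e > H:
            fates.append(SeedFate(i, float(depth), g, None, UNRESOLVED))
            continue
        if n_enc_blocked > 0:
            fates.append(SeedFate(i, float(depth), g, None, "blocked_aggregate"))
            continue
        if surface_blocked:
            fates.append(SeedFate(i, float(depth), g, None, "blocked_aggregate"))
            continue

        # crust check at surface arrival
        if crust[e - 1] in (CRUST_ABSENT, CRUST_WET):
            fates.append(SeedFate(i, float(depth), g, e, "emerged"))
            continue
        emerged_day = None
        for d in range(e + 1, min(e + crust_wait_days, H) + 1):
            if crust[d - 1] == CRUST_WET:
                emerged_day = d
                break
        if emerged_day is not None:
            fates.append(SeedFate(i, float(depth), g, emerged_day, "emerged"))
        else:
            fates.append(SeedFate(i, float(depth), g, None, "blocked_crust"))

    daily = np.zeros(H, dtype=int)
    for f in fates:
        if f.emergence_day is not None:
            daily[f.emergence_day - 1] += 1
    daily_emerged = np.cumsum(daily)
    final_rate = 100.0 * daily_emerged[-1] / seedbed.n_seeds
    return SimulationResult(
        daily_emerged=daily_emerged,
        final_emergence_rate=float(final_rate),
        cause_partition=cause_partition(fates),
        fates=fates,
        rng_seed=rng_seed,
    )


@dataclass
class ReplicateSummary:
    n_replicates: int
    final_rate_mean: float
    final_rate_sd: float
    cause_mean: dict[str, float]
    cause_sd: dict[str, float]


def replicate_simulations(
    cfg,
    weather: WeatherSeries,
    germ: CultivarGerminationParams,
    elong: ElongationParams,
    n_replicates: int = 10,
    horizon_days: int | None = None,
    master_seed: int | np.random.SeedSequence = 0,
    germination_window_days: int = GERMINATION_WINDOW_DAYS,
    crust_wait_days: int = 7,
) -> tuple[list[SimulationResult], ReplicateSummary]:
    """Run independent replicate simulations, rebuilding the seedbed each time.

    Each replicate gets its own random-number substream derived from the
    master seed (one for seed placement, one for the simulation), so the set
    of replicates is reproducible as a whole.
    """
    from .seedbed import build_seedbed

    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    base = (
        master_seed if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    results = []
    for child in base.spawn(n_replicates):
        bed_ss, sim_ss = child.spawn(2)
        seedbed = build_seedbed(cfg, np.random.default_rng(bed_ss))
        update_crust(seedbed, weather, cfg)
        results.append(run_simulation(
            seedbed, weather, germ, elong,
            horizon_days=horizon_days, rng_seed=sim_ss,
            germination_window_days=germination_window_days,
            crust_wait_days=crust_wait_days,
        ))
    finals = np.array([r.final_emergence_rate for r in results])
    causes_present = sorted({c for r in results for c in r.cause_partition})
    cause_mat = {
        c: np.array([r.cause_partition.get(c, 0.0) for r in results])
        for c in causes_present
    }
    sd = float(np.std(finals, ddof=1)) if n_replicates > 1 else 0.0
    summary = ReplicateSummary(
        n_replicates=n_replicates,
        final_rate_mean=float(np.mean(finals)),
        final_rate_sd=sd,
        cause_mean={c: float(np.mean(v)) for c, v in cause_mat.items()},
        cause_sd={
            c: (float(np.std(v, ddof=1)) if n_replicates > 1 else 0.0)
            for c, v in cause_mat.items()
        },
    )
    return results, summary
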