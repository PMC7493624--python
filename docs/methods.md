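# Methods

This note records the modelling choices behind `soyemerge`: the procedure,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer would want written down.

## Germination parameter estimation

Cumulative germination fractions are summarised per incubation level with a
three-parameter Gompertz curve g(t) = A·exp(−exp(−k(t − t_m))). This
parameterisation was chosen because its closed-form inverse
t_p = t_m − ln(−ln(p/A))/k gives percentile times directly; A is the final
germination fraction (the germinable fraction when fitted on the pooled
thermal-time curve). Replicates are pooled by concatenating their
(time, fraction) points before fitting — with a shared scoring schedule this
equals fitting replicate-summed counts, and with 25 seeds per dish a
per-replicate fit would be too noisy to average usefully. Fits use a
data-driven initial guess with up to 10 seeded random restarts on
non-convergence; bounds are A ∈ (0, 1], k > 0.

**Base temperature.** For each percentile p ∈ {20, 40, 50, 60, 80, 90},
ordinary least squares of rate 1/T_p against temperature over the
sub-optimal range; T_b is the unweighted mean of the per-percentile
x-intercepts (the full set is reported alongside). The "linear range" is
selected automatically as the largest contiguous set of temperatures at or
below the rate peak for which every percentile regression reaches R² ≥ 0.95
(threshold configurable, range overridable with an explicit list). If no
window qualifies, the best available window is used and a warning recorded.
When rates decrease monotonically from the coldest level (no sub-optimal
branch exists) the full range is regressed so the non-positive slope
surfaces as an explicit estimation error rather than a silent result.

**Optimum temperature.** A unimodal beta-type response
r(T) = r_max·((T_max−T)/(T_max−T_opt))·((T−T_min)/(T_opt−T_min))^e with
e = (T_opt−T_min)/(T_max−T_opt) is fitted to the median-percentile rate
(1/T50); T_opt is a fit parameter and the curve's argmax. The exact
functional family used for the original cultivar estimates is not published;
this beta form is the standard choice for cardinal-temperature fits, and the
estimator is isolated so the family can be swapped. A fitted optimum outside
the observed range falls back to the data argmax with a boundary warning.

**Base water potential.** Same x-intercept construction against water
potential at a single temperature (20 °C). The assay description in the
source protocol says rates were regressed on "temperature" in the osmotic
context; this is read as a typo for water potential — the regression here is
on ψ. Per-percentile x-intercepts are reported so the expected spread (most
negative ψ_b for the fastest seeds) is visible; the summary value is their
unweighted mean.

**Thermal-time distribution.** Courses within the pooled linear range are
mapped to thermal time (T − T_b)·t (constant incubator temperature per
course), pooled, fitted with one Gompertz curve, and its normalised CDF is
discretised into 5 °Cd classes over 0–60 °Cd (both configurable). A collapse
diagnostic reports the RMS deviation between per-level curves interpolated
on a common grid, warning above 0.05. Sampling from the class distribution
draws a class and then a uniform value within it, so a zero-width class acts
as a point mass (used for deterministic traces).

## Seedbed and weather

The seedbed is modelled as a 1-D depth column per seed plus a statistical
aggregate-encounter process, not a literal voxel grid: encounter rates are
derived from aggregate areal densities, which suffices for every output the
package reports (per-seed fates, emergence curves, cause partitions). Seeds
draw depths i.i.d. from a truncated normal (default 3.0 ± 0.7 cm, truncated
to 1–6 cm) or from explicit depth classes. Soil layers are fixed at 0–3,
3–5 and 5–10 cm; a depth maps to the layer containing it, with the boundary
belonging to the deeper layer.

Crust formation is a single threshold event on cumulative rainfall since
sowing. The thresholds per crusting class — non-crusting ∞, moderately
crusting 25 mm, highly crusting 15 mm — and the wet-crust criterion (same-day
rainfall ≥ 2 mm) are calibration knobs with provisional defaults: the
dependency structure is established, but the numeric values are not
published, so they are exposed in `SeedbedConfig`. Once present the crust
persists for the whole horizon.

The weekly water-status indicator classifies "no stress" at ≥ 10 mm
cumulative weekly rainfall, inclusive at the boundary.

## Emergence engine

Daily order of events: hydrothermal accrual → germination check →
post-germination water-stress check → growth → obstacle checks. Day 1 is the
first day after sowing; shoot growth starts the day after germination, so
emergence is always at least one day later than germination.

Per-seed randomness (germinability Bernoulli, thermal-time requirement,
aggregate encounters and block outcomes) is drawn once per seed from a
dedicated substream indexed by seed id and spawned from the run seed;
given those draws the daily trajectory is deterministic, which makes the
engine reproducible and lets tests inject degenerate distributions.

Buried-aggregate encounters are Poisson with mean
count/m² × π/4·(D + d_shoot)² × depth/10 cm per class (d_shoot = 0.5 cm
effective shoot width); each encounter blocks with the class probability,
and non-blocking encounters each add `pathway_detour_cm` (default 0.5 cm)
to the path. Surface aggregates are tested once at surface arrival.
Crust blocking is survival-based rather than one-shot: a shoot arriving
under a dry crust emerges on the first wet-crust day within
`crust_wait_days` (default 7) and is blocked permanently otherwise.

Elongation defaults (L_max = 8 cm, r = 0.02 /°Cd, radicle 0.08 cm/°Cd,
growth base temperature 4 °C, default block probability 0.1) are plausible
soybean-scale values chosen once; they are inputs in any real application
and every one is a constructor argument.

Two conflations are deliberate: intrinsic non-germinability (Bernoulli at
sowing) and failure to germinate within the 30-day window are both ledgered
as `non_germination`, matching how the cause is reported. A seed still
elongating (or still waiting under a dry crust with the wait window
truncated) when the weather series ends receives the explicit fate
`unresolved_horizon` rather than being forced into a cause; with the
recommended horizon (≥ 45 days) this never occurs, and the cause partition
sums to 100 % either way.

## Evaluation statistics

EF, RMSEP and MD are computed exactly as defined above; the identity
EF = 1 − n·RMSEP²/Σ(O−Ō)² is used as a cross-check in tests. EF is undefined
(an error) when observations have zero variance. Emergence classes use
strict `< 50` for poor, so both boundaries (50, 75) belong to "good".
Observed courses at irregular dates are paired with the simulated daily
curve by direct lookup at the observation day — whether statistics are
computed at observation dates only or over a full course is thereby explicit
in what the caller passes. The degree-day helper clamps sub-base days to
zero so cumulative thermal time never decreases.

## Synthetic data

The generators define the study conditions for every test:

- **Lab courses**: 4 replicates × 25 seeds per level by default; each seed
  draws a speed quantile u, takes its thermal-time requirement as the
  u-quantile of the true distribution and (for osmotic series) a base water
  potential comonotone with u — fast seeds get the most negative ψ_b, which
  is exactly the coupling under which the per-percentile x-intercept
  estimator is consistent. Osmotic rates scale linearly as
  (ψ − ψ_b)/(0 − ψ_b), the same linear rate-reduction the estimator assumes,
  rather than a full hydrothermal-time model. Scoring is every 8 h (three
  times daily) until germination stalls, capped at 21 days (a Petri assay is
  closed once stalled). Cumulative counts at scoring times are exact CDF
  evaluations, so the discretised scoring schedule does not bias the fits.
- **Weather**: AR(1) temperature noise around a template mean and
  Bernoulli-gamma rainfall; layer potentials follow a wetness index that
  dries geometrically (fastest in 0–3 cm) and recharges with rain. Only
  envelope statistics are anchored to observed field conditions (spring
  sowing-depth temperatures of 11–17 °C; 30-day rainfall totals of
  34–125 mm, which the `warm_wet` template reproduces in ≥ 90 % of draws).
  The `no_stress` template is deterministic and non-limiting by
  construction. The generator does not attempt to reconstruct any specific
  site-year.
- **Seedbed templates**: soil types map to crusting classes (clay and silty
  clay non-crusting; silty loam highly crusting; the intermediate loams
  moderately crusting) with a common coarse conventional-tillage aggregate
  spec (invented densities: 400/m² at 2 cm and 150/m² at 4 cm buried,
  100/m² at 3 cm on the surface).

Cultivar presets encode published lab values (T_b 4 / 3 / 3.5 °C, T_opt
28 / 30 / 30 °C, mean ψ_b −0.58 / −0.56 / −0.71 MPa, germinable fraction
0.97 / 0.99 / 0.97, median thermal time 18 °Cd with nearly all mass below
40 °Cd). The per-percentile ψ_b spread is 0.35 MPa, chosen so the preset
span covers the published fastest-to-slowest range and germination at
−0.50 MPa is strongly reduced, while the mean over the six percentiles
equals the published mean exactly.

What passing tests therefore show: the estimators recover the parameters of
data generated under their own structural assumptions (linear rate
responses, constant incubator temperatures, binomial sampling), and the
engine obeys its conservation laws and limiting cases. They do not show
robustness to field realities the generators omit: diurnal temperature
cycles, sensor error, non-linear rate responses near the optimum, seed lot
heterogeneity beyond the one-dimensional speed quantile, or spatially
structured aggregates.

## Problem sizes

The default protocol follows the published design — 10 replicate simulations
of 1000 seeds per cultivar × condition — which runs in well under a second
per cell. Parameter-recovery checks use 200 synthetic datasets per
estimator (4 temperatures or 4 water potentials, 4 × 25 seeds each), enough
for the mean-recovery bounds (±0.5 °C for T_b, ±0.05 MPa for ψ_b, ±0.02 for
the germinable fraction) to be comfortably resolved.

## Known limitations

- Crust thresholds and the wet/dry criterion are provisional calibration
  values, not measurements.
- The aggregate model is statistical; it reproduces blocking rates, not the
  geometry of individual clods, and its default densities/probabilities are
  illustrative.
- The hydrotime treatment is a linear rate-reduction, adequate for
  x-intercept estimation but not a mechanistic hydrothermal-time model.
- Soil temperature and water potential are inputs; no heat or water
  transfer is simulated.
- High-temperature injury, waterlogging and biotic stresses are explicitly
  out of scope.
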