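# soyemerge

Stochastic, seed-by-seed simulation of soybean germination and seedling
emergence in virtual seedbeds, with the laboratory parameter-estimation and
model-evaluation chain around it.

Sowing soybean early — into colder, wetter seedbeds — is an attractive lever
against late-summer drought, but only if the crop still emerges well.
`soyemerge` is aimed at crop modellers and agronomists who want to predict
field emergence rates and diagnose *why* seedlings fail: it follows every
sown seed through germination, early water stress, shoot elongation past
soil aggregates, and a rainfall-driven surface crust, and ledgers each seed
as emerged or lost to one of four causes (non-germination, post-germination
water stress, blocked by aggregates, blocked by a crust).

## The model in brief

**Germination.** Seed *i* needs a thermal time θᵢ (°Cd) drawn from the seed
lot's distribution. Hydrothermal time accrues daily as max(0, T_d − T_b),
but only on days when the water potential ψ of the seed's soil layer exceeds
the base potential ψ_b. Germination occurs when the accrual reaches θᵢ;
seeds not germinated within 30 days never germinate. A fraction
1 − g (g = germinable fraction) of the lot is intrinsically non-germinable.

**Early water stress.** On the two days after germination, if ψ in the layer
the radicle has reached falls below ψ_b, the seedling dies the next day.

**Emergence.** The hypocotyl elongates as L(TT) = L_max·(1 − e^(−r·TT)) in
thermal time above a growth base temperature, along a path equal to the
sowing depth plus a detour per circumvented buried aggregate. Encountered
aggregates block with class-specific probabilities; a crust (formed once
cumulative rainfall passes a soil-class threshold) lets shoots through only
on wet-crust days.

**Parameter estimation.** From Petri-dish time courses, cumulative
germination is fitted with a Gompertz curve g(t) = A·exp(−exp(−k(t − t_m)));
germination rates 1/T_p (p = 20…90 %) regressed on temperature give T_b as
the x-intercept, a beta-type response fit gives T_opt, and the same
x-intercept construction against water potential gives ψ_b. Pooling courses
on the thermal-time axis yields the distribution of θ and the germinable
fraction.

**Evaluation.** Predicted vs observed emergence courses are compared with
model efficiency EF = 1 − Σ(P−O)²/Σ(O−Ō)², RMSEP = √(Σ(P−O)²/n) and mean
deviation MD = mean(P−O), plus poor/good/very-good classes of final rates.

## Worked example

Simulate 1000 seeds of cv. Ecudor (lab values: T_b = 4 °C, ψ_b = −0.58 MPa,
germinable fraction 0.97, median thermal time 18 °Cd) in a non-limiting
seedbed:

```python
import soyemerge as se

germ = se.preset_cultivar_params("Ecudor")
cfg = se.SeedbedConfig(n_seeds=1000, aggregate_spec=[],
                       soil_crusting_class="non_crusting")
weather = se.generate_weather("no_stress", 45)
results, summary = se.replicate_simulations(
    cfg, weather, germ, se.ElongationParams(),
    n_replicates=10, master_seed=1)
print(f"final emergence {summary.final_rate_mean:.2f} +/- {summary.final_rate_sd:.2f} %")
print("causes:", {k: round(v, 2) for k, v in summary.cause_mean.items()})
```

prints

```
final emergence 96.99 +/- 0.39 %
causes: {'blocked_aggregate': 0.0, 'blocked_crust': 0.0, 'emerged': 96.99,
 'non_germination': 3.01, 'post_germination_water_stress': 0.0}
```

With nothing limiting germination or growth, the only losses are the 3 % of
seeds the lab assay says cannot germinate — the simulated non-germination
share passes the lab germinable fraction straight through. On a crust-prone
silty loam (`se.seedbed_templates("silty_loam")`) with `"crust_prone"`
weather, `blocked_crust` and `blocked_aggregate` become the dominant causes
instead.

The same pipeline is scriptable from the shell:

```bash
soyemerge synth weather --template crust_prone --seed 3 --out weather.csv
soyemerge synth seedbed --template silty_loam --out bed.yaml
soyemerge fit-lab --input lab.csv --cultivar Ecudor --out ecudor.json
soyemerge simulate --seedbed bed.yaml --weather weather.csv \
    --params ecudor.json --n-seeds 1000 --replicates 10 --seed 42 --out run/
soyemerge evaluate --observed obs.csv --simulated run/daily_curve.csv --out stats.json
soyemerge run-protocol --manifest manifest.yaml
```

## Layout

- `soyemerge.germination` — Gompertz fits, percentile rates, T_b / T_opt /
  ψ_b estimation, thermal-time distribution, lab CSV I/O.
- `soyemerge.seedbed` — seedbed configs, seed/aggregate placement, weather
  series, crust dynamics, weekly water-status indicator.
- `soyemerge.engine` — the per-seed simulation and replicate summaries.
- `soyemerge.evaluation` — EF / RMSEP / MD, emergence classes, course
  alignment, degree-day helper.
- `soyemerge.synthetic` — generators for lab courses, weather and seedbed
  templates with known ground truth; cultivar presets.
- `soyemerge.protocol`, `soyemerge.cli` — manifest-driven orchestration and
  the `soyemerge` command.

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
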