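# internode

A daily-step simulator of main-stem internode growth in greenhouse
cucumber (*Cucumis sativus*), coupling a light response of final internode
length to a normalized Arrhenius-type temperature response of
developmental rates and durations.

## The problem

Internode length shapes how light is distributed through a canopy, and in
cucumber it responds to the light quantity (PAR) and quality (R:FR) the
organ perceives during its fastest growth. Light-only internode models
are calibrated for a fixed 20 °C greenhouse; under realistic climates,
where daily mean temperature drifts between the heating set-point (20 °C)
and the ventilation threshold (24 °C), temperature changes both *when*
internodes appear — and therefore which light they see — and *how fast and
for how long* they elongate. This package implements the
temperature-sensitive extension and the machinery to compare it with the
fixed-20 °C baseline, attribute length differences to light versus
temperature, and evaluate predictions against length-by-rank
measurements.

## The model

A single normalized Arrhenius-type response drives every
temperature-dependent process:

```
F(T) = A · T · exp(−ΔH_A/(R·T)) / (1 + exp(−ΔH_A/(R·T))^(α·(1 − T/T₀)))
F_av(T) = F(T) / F(20 °C)
```

with the 18-species average parameters ΔH_A = 69 350 J mol⁻¹, T₀ = 305 K,
α = 3.5 (the scaling coefficient A cancels in the ratio and is never
computed). F_av multiplies rates and divides durations:

- **Appearance** — a development accumulator gains `F_av(T_today)/D_a20`
  leaves per day (phyllochron `D_a20 = 1.4 d` at 20 °C); each integer
  crossed creates an internode at 3 cm.
- **Target length** — `FIL_T = F_av(T4d) · (13.4 − 0.014·PAR4d + f(R:FR))` cm,
  where PAR4d and T4d are means over the 4 days starting 6 days before
  the internode appeared, and f(R:FR) is a pluggable light-quality hook
  (default 0).
- **Elongation** — first-order approach `dL = k·(FIL_T − L)` per day with
  k = 0.5 d⁻¹, for a fixed duration `D_e(T) = 4.2 d / F_av(T4d)`, after
  which the length freezes.

The temperature-insensitive baseline (scenario "MA-20") is the same code
path with F_av ≡ 1. Evaluation statistics follow the mean-squared-deviation
decomposition: RMSD, bias, and SPE = 100·bias²/RMSD². A synthetic
greenhouse-climate generator (AR(1) PAR, set-point/ventilation-clipped
temperature; presets `E1`, `E2`) makes every component runnable without
measured data.

## Worked example

```
$ internode genclimate --preset E1 --days 45 --seed 42 --out climate.csv
wrote 45 days to climate.csv (PAR mean 475, T mean 21.9 degC)
$ internode simulate --climate climate.csv --steps 29 --scenario ma-t --out run/
ma-t: 23 internodes after 29 steps -> run
$ internode compare --climate climate.csv --steps 29 --out cmp/
MA-T 23 vs MA-20 20 internodes; mean FIL delta 1.35 cm -> cmp
```

The synthetic climate emulates the first greenhouse experiment's summary
statistics (PAR 464 ± 116 μmol m⁻² s⁻¹, mean temperature 21.9 °C). After
29 daily steps the temperature-sensitive run carries 23 internodes versus
20 for the fixed-20 °C baseline — warmer-than-reference days accelerate
appearance — and its internodes are on average 1.35 cm longer, because
F_av > 1 raises each length target. `run/internodes.csv` records, per
internode, the fixed signals and outcomes:

```
rank,appearance_day,par4d,t4d,fav,fil_light,target_cm,duration_d,final_cm,active
3,5,438.273,22.2074,1.21874,7.26418,8.85316,3.44618,8.28474,False
```

Internode 3 appeared on day 5, perceived PAR4d ≈ 438 μmol m⁻² s⁻¹ and
T4d ≈ 22.2 °C, giving F_av ≈ 1.22: its light-only length of 7.26 cm was
raised to a target of 8.85 cm, reached in a 3.45-day elongation window
(shortened from 4.2 d), freezing at 8.28 cm. `cmp/attribution.csv` splits
each rank's MA-T − MA-20 length difference into a PAR-signal-shift
component, a direct temperature component and a residual, together with
the appearance-day advance (up to 4 days earlier at high ranks in this
run).

The temperature response itself can be tabulated directly:

```
$ internode response --from 20 --to 24 --step 1
temperature_C,F_av
20,1
21,1.09629
22,1.19734
23,1.30137
24,1.40565
```

so a constant 24 °C shortens the phyllochron from 1.4 d to
1.4/1.41 ≈ 1.0 d.

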