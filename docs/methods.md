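# Methods

## Model structure and assumptions

The simulator advances a single cucumber main stem on 1-day steps. Two
state components exist: a continuous development accumulator (in leaves)
and an ordered collection of internodes, each carrying its fixed
environmental signals and a length trajectory. The run starts at step 2
with the accumulator at 1 and the first internode present at 3 cm (the
first true leaf stage); step 1 is not represented — nothing in the model
depends on it.

Each day, in order:

1. **Development.** The accumulator gains `F_av(T_today)/D_a20` leaves,
   using the current day's mean air temperature — appearance responds to
   temperature day by day, not through a window. Every integer threshold
   crossed creates one internode at 3 cm; fractional progress carries
   over, and multiple crossings in one day each create an internode
   (possible only near the response optimum ~29 °C, but handled).
2. **Signal fixing.** At appearance, the organ's PAR4d and T4d are
   computed as means over the inclusive day window `[d−6, d−3]` (4 days
   starting 6 days before appearance). Under first-order elongation the
   growth rate is maximal at appearance, so "maximum growth rate" and
   appearance coincide and a single event time anchors the window. The
   light target `FIL = max(3, 13.4 − 0.014·PAR4d + f(R:FR))`, the
   temperature-scaled target `F_av(T4d)·FIL` and the elongation duration
   `D_e = 4.2/F_av(T4d)` d are fixed once and never recomputed:
   within-growth temperature fluctuation is deliberately outside the
   model.
3. **Elongation.** Every active internode (except those created the same
   day) adds `max(0, k·(target − L))` with k = 0.5 d⁻¹. Negative
   increments are clamped — organs do not shrink when a target sits below
   the current length (possible after the floor clamp).
4. **Termination.** An internode elongates for exactly `D_e` days and
   then freezes. A non-integer duration ends with a partial day whose
   increment is scaled by the remaining fraction (e.g. 0.2 of a day for
   D_e = 4.2); always flooring the duration instead would bias every
   final length downward by up to half a day of growth, so the
   fractional rule is the default and `fractional_final_step=False`
   restores floor behaviour. Freezing by elapsed duration, not by
   reaching 95 % of the target, is the defining rule; with the default
   k and D_e the residual deficit at freezing is ~5 % anyway.

The temperature-insensitive baseline ("MA-20", the original fixed-20 °C
model) is the identical code path with F_av forced to 1 in every role
(appearance, target, duration), so at a constant 20 °C the two scenarios
are bit-identical — an asserted invariant.

## Temperature response

`F_av(T) = F(T)/F(20 °C)` with
`F(T) = T·exp(−ΔH_A/(R·T)) / (1 + exp(−ΔH_A/(R·T))^(α(1−T/T₀)))`.
Defaults are the 18-species averages ΔH_A = 69 350 J mol⁻¹, T₀ = 305 K,
α = 3.5; no cucumber-specific calibration exists, and the shipped species
table contains only this average entry (others can be supplied via
config). The scaling coefficient of the un-normalized curve cancels in
the ratio and is never computed. The denominator exponent is evaluated
directly in log space because `exp(−ΔH_A/RT)` is ~1e−13 at room
temperature and exponentiating it would lose precision. Temperatures are
Celsius at every public interface (all inputs are Celsius) and converted
internally. Outside 0–40 °C the factor is an extrapolation and a warning
is issued; outside −20–60 °C evaluation refuses. No hard developmental
base temperature is imposed — the 10 °C base appears only inside the
thermal-time identity `D_e20 = 42 °Cd / 10 °C = 4.2 d`; below ~12 °C the
curve decays smoothly rather than cutting off, a documented divergence
from degree-day formulations.

A known reporting subtlety: at the organ-level mean temperatures of the
two greenhouse experiments the point evaluations are F_av(21.2) = 1.116
and F_av(22.8) = 1.280, while averaging rank-specific factors (a convex
function of temperature) gives ~0.01 more at the second experiment's
spread — Jensen's inequality. The package implements point evaluation;
comparisons against rank-averaged figures should allow ±0.01.

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| `fil_intercept` | 13.4 | cm | light-response intercept of final length |
| `fil_par_slope` | 0.014 | cm/(μmol m⁻² s⁻¹) | length decrease per unit PAR4d |
| `k_elong` | 0.5 | d⁻¹ | first-order approach rate to the target |
| `De20` | 4.2 | d | elongation duration at 20 °C |
| `Da20` | 1.4 | d | phyllochron at 20 °C (1/0.7 d⁻¹) |
| `initial_length` / `fil_floor` | 3 | cm | appearance length; lower clamp of targets |
| `analysis_min_rank` | 5 | – | lowest rank entering summaries (lower ranks form pre-experiment) |
| `arrhenius.*` | 69350 / 305 / 3.5 / 20 | J mol⁻¹, K, –, °C | response parameters and reference |
| `window` | 6 before, width 4 | d | PAR4d/T4d signal window |

The f(R:FR) light-quality term is a code-level hook `(rank, day) → cm`,
default 0: the ray-traced canopy from which R:FR emerges is outside this
package's scope, so light-quality contributions enter only if the user
supplies them.

## Signal-window edge handling

Windows of early internodes predate the climate record (the simulation
starts at step 2, the window reaches 6 days back). Days before the series
start are dropped and the mean is taken over what remains; if nothing
remains, the first recorded day's value is used. Truncation is logged.
For any event at least 7 days after the series start the clamping
provably never activates (asserted in tests). Day indices are plain
consecutive integers with no calendar semantics.

## Scenario comparison and attribution

`compare_scenarios` runs both scenarios on the same climate and, per rank
present in both, splits `ΔFIL = FIL(MA-T) − FIL(MA-20)` into

- `par_component = −0.014·(PAR4d_MA-T − PAR4d_MA-20)` — the part caused by
  temperature-shifted appearance moving the light window;
- `temp_component = (F_av(T4d)−1)·FIL_light` — the direct scaling of the
  target, evaluated with the temperature-sensitive run's signals;
- `residual = ΔFIL − par − temp` — interaction, clamping and
  unfinished-elongation effects; zero by construction when F_av = 1 and
  the windows coincide.

The PAR share `100·|par|/|ΔFIL|` is reported only when |ΔFIL| > 0.1 cm;
below that the ratio is noise.

## Evaluation statistics

With error e = simulated − measured over the rank intersection (counts
differ routinely; intersection never invents data): bias = mean(e),
RMSD = √mean(e²), SPE = 100·bias²/RMSD² — the systematic share of the
mean squared deviation, since MSD = bias² + var(e) in population form (an
asserted identity). CV uses the sample SD (n−1). Pearson's r requires ≥3
pairs and nonzero variance. Ranks below `analysis_min_rank` are excluded
before pairing.

## Synthetic climate generator

A phenomenological emulator, not a greenhouse physics model: it exists so
that the full pipeline is exercisable with realistic inputs. Daily PAR is
a stationary AR(1) Gaussian process (lag-1 autocorrelation 0.5 — weather
persistence is plausible but unmeasured, and exposed in config) truncated
at 0; the target mean sits ~4 SD above zero so truncation is negligible.
Temperature is the period mean plus a sunny-day warming term
(0.005 °C per μmol m⁻² s⁻¹ of PAR anomaly) plus Gaussian noise
(SD 0.8 °C), clipped between the 20 °C heating set-point and 0.5 °C above
the 24 °C ventilation threshold — the set-point/ventilation mechanism
reduced to clipping. The coupling and noise values were chosen once so
realized daily means span roughly 20–24 °C, the band a vented greenhouse
with those set-points realizes. Presets `E1` (PAR 464 ± 116
μmol m⁻² s⁻¹, mean 21.9 °C) and `E2` (404 ± 120, 22.4 °C) encode the two
experimental periods; day/night set-point structure is not resolved
because the model consumes daily means only.

What the generator does **not** emulate: sub-daily dynamics, solar
seasonality and day-length trends, spells of overcast weather longer than
the AR(1) memory, greenhouse transmission (inside-PAR is generated
directly), and any correlation structure beyond first order. Tests
passing on synthetic climate therefore demonstrate correctness of the
mechanism, not predictive skill on measured data.

## Numerical choices and problem sizes

Everything is deterministic given climate + config; all randomness in
tests and the generator flows from explicit seeds. Integer-threshold
crossing uses a 1e-9 tolerance so accumulated floating error cannot delay
an appearance by a day. Simulation tests run 30–105 daily steps with at
most ~100 internodes — the regime the model describes — and the whole
suite completes in a few seconds. Appearance-interval convergence is
checked over ~100 days against `D_a20/F_av(T)` (empirical interval within
the 1-day discretization, in practice within 0.1 d).

## Known limitations

- No day/night temperature differential (DIF) effects: daily means only.
- Air temperature stands in for meristem temperature; deviations of up to
  ±4 °C between the two are documented for cucumber.
- The 18-species-average Arrhenius parameters are a rough stand-in for a
  cucumber-specific calibration, best supported between 20 and 24 °C.
- Signals are frozen at appearance; temperature during growth itself has
  no effect on an internode once its target and duration are set.
- No canopy geometry, leaf growth, dry matter or emergent R:FR.
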