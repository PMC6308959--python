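# Methods

This note records the model, default parameters, and numerical choices of
the `whdd` package: the two sensor-filter cascades, baseline acquisition,
the fuzzy risk controller, the session simulator, and the packet/alert
pipeline.  It documents what the shipped defaults do and, where a design
choice was not forced, why it was made.

## 1. Heart-rate filter cascade (`whdd.filters`)

The heart-rate channel is conditioned in three stages, applied per
2 Hz sample.

**Threshold stage.**  A sample is accepted only inside the plausible band
`[hr_lower, hr_upper]`, defaulting to [50, 190] bpm.  The upper bound is
the Tanaka maximum heart rate HRMax = 208 − 0.7 · age, rounded
half-away-from-zero; at the reference age of 26 this is
round(189.8) = 190.  `FilterConfig(age=...)` recomputes the bound for
another wearer.  An out-of-band sample is replaced by the previous stored
slot value, so the output stream never leaves the band.

**Error stage.**  The inter-sample error is
`error = value − window[count − 1]` (the previously stored value).  Two
asymmetric corrections apply:

* `error < −10` (sudden drop, e.g. a dropout read as 0): corrected to
  `value − round(error × 1.05)`, i.e. slightly more than the full drop is
  added back, while a run-length counter `mincount` stays ≤ 6;
* `error > +25` (sudden spike, e.g. a motion artifact): corrected to
  `value − round(error × 0.6)`, removing 60 % of the jump, while
  `maxcount` stays ≤ 2.

When a budget is exhausted the sample is replaced by the previous slot
value outright and the counter resets — a long run of "artifacts" is by
then more plausibly a genuine physiological change, and holding the last
value bounds the damage either way.  Errors in the dead band
[−10, +25] pass through unchanged (exercise onset raises heart rate
quickly, so the dead band is wider upward than downward).

**Window stage.**  Stored samples accumulate in a 60-slot window whose
slot 0 is seeded: initially with the resting baseline heart rate, and
after each emitted mean with that mean.  A window therefore accepts 59
new samples before emitting `mean(window)` and restarting.  Seeding makes
the very first window well-defined without a cold-start special case and
carries one window's summary into the next as a mild prior.

Rounding throughout is half-away-from-zero
(`copysign(floor(|x| + 0.5), x)`), matching fixed-point firmware
conventions rather than Python's banker's rounding.

## 2. Body-temperature cascade (`whdd.filters`)

**Skin-to-core conversion.**  The wrist sensor reads skin temperature;
core temperature is estimated as

    T_core = T_skin + α · (T_skin − T_amb)

with a body-part heat-transfer coefficient α.  The shipped table
`BODY_PART_ALPHA` covers rectal 0.0699, head 0.3094, torso 0.5067,
hand 0.7665 (the default — the device is wrist-worn), foot 2.1807.

**Sweat compensation.**  Evaporative cooling biases the skin reading low,
so converted values in the compensation band are pushed back up:

    T_fix = T_core + (35 − T_core) × 1.5        for T_core ∈ [31, 35]

which is the affine map 52.5 − 0.5 · T_core, carrying [31, 35] onto
[37, 35] (decreasing: the colder the reading, the larger the assumed
evaporative loss).  Values in the identity band (35, 40) pass through.
Anything else — sensor fault, detached device — falls back to a nominal
36.0 °C so downstream logic always receives a value in the physiological
range.  The output is continuous at 35 °C (both branches give 35) and is
always inside [35, 40).

The default compensation band is [31, 35]; a wider [28, 35] variant is
available by constructing `FilterConfig(comp_band=(28.0, 35.0))` — the
two bands coexist in source material for such devices and the narrow one
was chosen as the default because it is the one consistent with the
compensation formula's fixed point at 35.

**Hold rule and window.**  The temperature path mirrors the heart-rate
window (60 slots, seeded slot 0, here with 36.0 °C).  A store-side hold
rule only writes a new value when the deviation `35 − T` differs from the
stored `temp_diff`, suppressing redundant writes of an unchanged reading;
it can be disabled via `FilterConfig(enable_hold_rule=False)`.  The
comparison is exact float equality, deliberately: the rule exists to
deduplicate literally repeated sensor words, not nearly-equal ones.

## 3. Baseline acquisition (`whdd.baseline`)

Before a run, each channel is averaged over one resting minute —
`BASELINE_SAMPLES = 120` samples at 2 Hz.  The attempt is valid when the
average is finite, nonzero, and inside the adult resting range
(heart rate 50–90 bpm, skin conductance 10–50 μS).  Individual zero
samples within a minute are kept (they dilute the average but are
informative of sensor contact); only an all-zero or out-of-range *mean*
triggers a re-measurement, up to `max_attempts` (default 3), after which
`AcquisitionError` reports the channel, attempts used, and last average.
Each attempt consumes exactly 120 samples from the stream, which the
acceptance suite asserts by counting.

## 4. Fuzzy risk controller (`whdd.risk`)

Risk is a Mamdani fuzzy controller over four crisp inputs:

| input          | universe   | terms (peaks)                              |
|----------------|-----------|---------------------------------------------|
| `heart_rate`   | [50, 200] | low / medium / high at (relax_hr, mid, HRMax) |
| `body_temp`    | [35, 40]  | normal / elevated / high at (36.2, 37.8, 39.4) |
| `gsr_delta`    | [−30, 10] | large_drop / mild_drop / stable at (−20, −10, 0) |
| `danger_coeff` | [20, 45]  | mild / hot / severe at (25, 32, 38)         |

`gsr_delta` is the skin-conductance change from the resting baseline
(sustained sweating drains measured conductance on this sensor, so large
negative values indicate heavy sweating).  `danger_coeff` is the
environmental index `ambient °C + RH % / 10` — e.g. 23.5 °C at 80 % RH
gives 31.5, and 28.9 °C at 68.2 % RH gives 35.72.

Each input uses three piecewise-linear terms forming a partition of
unity (memberships sum to 1 everywhere on the universe), evaluated with
`np.interp`.  The output universe is the risk indicator [0, 40] with four
terms centred in the alert zones — Safe [0, 10], Attention (10, 20],
Warning (20, 30], Dangerous (30, 40] — as a shouldered trapezoid, two
triangles, and a shouldered trapezoid.

**Rule base.**  All 3⁴ = 81 antecedent combinations are enumerated and
each is mapped to an output term through a severity score: term indices
(0/1/2 per input) are weighted `heart_rate: 4, body_temp: 2, gsr_delta: 1,
danger_coeff: 1` and the total (0–16) is bucketed at edges (2, 6, 10)
into safe / attention / warning / dangerous.  Heart rate carries the
largest weight because it is the fastest and most reliable strain signal
on this sensor set; generating the table from a score keeps the rule base
consistent (monotone in every input by construction) and auditable.

**Inference.**  The default composition is product t-norm for rule
activation and activation-scaled *additive* aggregation of the output
terms, followed by centroid defuzzification on an 801-point grid with
`np.trapezoid` ("product–sum–gravity").  Classic min/max Mamdani is
available via `FuzzyConfig(tnorm="min", aggregation="max")` but is not
the default: with max aggregation the clipped output sets overlap and the
centroid develops small non-monotone ripples (dips of up to ~0.6 risk
points near term crossovers, e.g. around 38.6 °C), which would let a
*hotter* reading momentarily score *lower*.  The additive variant is
verified monotone in heart rate and temperature across a broad input
grid by the test suite.  When no rule fires with positive mass the
controller returns 0.

`default_fuzzy_config(relax_hr, age)` personalises the heart-rate terms
to the wearer (low peaks at the resting rate, high at the Tanaka
maximum).  Calibration anchors checked during design: resting inputs
score ≈ 5.4 (Safe); an extreme vector (190 bpm, 39.5 °C, −25 μS drop,
coefficient 36) scores ≈ 34 (Dangerous).

## 5. Session simulator (`whdd.simulate`)

The simulator produces a latent physiological truth and a corrupted
observation of it, so filter recovery can be measured against ground
truth.

**Protocols.**  `INDOOR_PROTOCOL`: 8 km/h × 10 min, 10 km/h × 2 min,
12 km/h × 3 min at 28.9 °C / 68.2 % RH (15 min → 1800 samples at 2 Hz).
`OUTDOOR_PROTOCOL`: 10 km/h × 12 min at 23.5 °C / 80 % RH.

**Latent dynamics.**  Heart rate relaxes first-order (τ = 35 s) toward a
stage target `relax_hr + intensity · (fitness · HRMax − relax_hr)` with
`intensity = clip(speed / 12, 0, 1)`.  Core temperature rises with
accumulated workload `w = Σ speed · dt` as
`36.8 + 2.8 · fitness · (1 − exp(−w / 4000))`; skin temperature is the
inverse of the conversion in §2, `(T_core + α · T_amb) / (1 + α)`.  Skin
conductance declines from baseline by
`18 · sweat_rate · (1 − exp(−w / 5000))` μS with a 1 μS floor.

**Observation model** (`ArtifactModel`).  Per-channel Gaussian noise
(heart rate σ = 2 bpm, skin temperature σ = 0.15 °C, conductance
σ = 0.5 μS); heart-rate spikes into [0, 49] ∪ [191, 220] with
probability 0.02; dropouts to 0 with probability 0.01; a sweat-dependent
skin-temperature depression of up to 0.8 °C.  `ArtifactModel.disabled()`
turns everything off.  Randomness derives from a
`numpy.random.SeedSequence`; `make_cohort` spawns independent child
sequences per runner, and each session spawns three per-channel streams,
so results are reproducible and runners are statistically independent.

**Events.**  A `feedback` event is logged when the latent heart rate
first reaches `discomfort_hr_frac × HRMax` — a proxy for the runner
pressing the discomfort button.

**Presets.**  `indoor_preset()` ships two comfortable profiles
(users 1–2: fitness 0.75, discomfort fraction 1.0, i.e. they never
report) and two strained profiles (users 3–4: fitness 0.93–0.95,
discomfort fractions 0.88/0.90).  The strained fitness values were set
during design so that the Dangerous transition lands inside the final
12 km/h stage rather than during the preceding warm-up — a protocol-
consistency constraint, fixed before the test suite was run against it.
The simulator emulates trend-level physiology for pipeline testing only;
it is not a validated thermoregulation model (no cardiovascular drift,
no humidity-dependent sweat efficiency, no individual acclimatisation).

## 6. Packets, comparison, and alert timing (`whdd.pipeline`)

Filtered epochs are grouped into packets of exactly
`PACKET_EPOCHS = 60` (30 s at 2 Hz); a 1800-sample session yields 30
packets, and a trailing partial window is counted in `dropped_epochs`
rather than silently discarded.  Each packet carries its window means,
from which a `RiskInputs` vector is built and assessed, producing one
risk/level row per window.

`compare_readings` computes signed and absolute mean errors between a
device series and a reference series of equal length.  `alert_timing`
reports the time of the first Dangerous assessment, the first feedback
event, and the lead `feedback − onset` (positive when the system alarms
before the wearer reports; `None` when either is absent).

## 7. Numerical conventions

* Rounding: half-away-from-zero everywhere a rounded integer is needed.
* Centroid grid: 801 points over [0, 40] (0.05 resolution), integrated
  with `np.trapezoid`; doubling the grid changes defuzzified values by
  < 0.01, well under the 0.1 display resolution.
* Band edges: the compensation band is closed [31, 35], the identity
  band open (35, 40); both branches agree at 35 so the cascade is
  continuous there, and 40 itself falls through to the 36.0 fallback.
* All configuration objects are frozen dataclasses validated at
  construction; invalid bands, gains, universes or rule tables raise at
  build time, not inference time.

## 8. Limitations

The package reproduces an algorithm, not a clinical claim: no assertion
is made about real-world heat-stroke detection performance.  Comparison
statistics in the test suite are computed over small static tables and
synthetic sessions; the simulator's parameters are plausible but not
fitted to human trial data; and the fuzzy controller's calibration
anchors are design targets verified by the tests, not measurements.
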