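# Methods

## Model

The respiratory system is a single linear compartment: resistance R
(cmH2O·s/L), compliance C (mL/cmH2O), baseline alveolar pressure PEEP_total.
With volume V above the end-expiratory baseline and inspiratory muscle
pressure Pmus ≥ 0 (stored nonnegative and *subtracted*, because muscle effort
lowers alveolar pressure), the equation of motion is

    Paw(t) = R·V̇(t) + V(t)/C + PEEP_total − Pmus(t).

The ventilator supplies the boundary condition. During inspiration, PSV/PCV
drive Paw along a first-order rise (time constant `rise_time_s`, default
0.1 s) to PEEP + set pressure; VCV prescribes a square-wave flow. During
expiration Paw = PEEP_set and the compartment relaxes with time constant
τ = R·C. Triggering is armed only in expiration after a refractory period
(default 0.2 s) and fires on a flow threshold (L/min), a pressure drop below
PEEP (cmH2O), or a mandatory-rate timer; any trigger resets the timer. PSV
cycles at a fraction of peak inspiratory flow (with a 150 ms lockout during
pressurization and a `max_insp_time_s` backstop); PCV/VCV cycle at the set
inspiratory time.

Efforts are half-sine (or ramp–hold–release) pulses, either at explicit onset
times or *entrained*: fired at each machine/auto-triggered insufflation onset
plus a fixed delay, which is the mechanism that produces reverse triggering.
Auto-trigger artifacts are biphasic flow blips (one sine period, 150 ms, zero
net volume) added to the *measured* flow channel only — a circuit disturbance
such as condensate oscillation, able to cross the flow trigger with Pmus
identically zero, but not part of lung flow.

## Numerics

The loop advances at the sampling rate (default 100 Hz, a ventilator-display
scale) with a trapezoidal (Crank–Nicolson) volume update solved jointly with
the boundary condition at each sample. For this linear ODE the scheme is
A-stable at any clinically plausible τ, and it was chosen over explicit
substepping because it makes two contracts hold exactly at every sample of a
noiseless export: the volume channel equals the cumulative trapezoid of the
flow channel, and the equation-of-motion residual is zero to float precision
(observed ≤ 3e-13 cmH2O across the battery; artifact samples deviate by
design, since the blip is a measurement disturbance). Trigger and cycling
decisions are taken at sample resolution using the previous-sample state
(≤ 10 ms latency, below all rule tolerances). Parameter combinations with a
nonpositive or sub-millisecond time constant are rejected before integration.

Measurement noise (Gaussian, seeded) is added only to the exported Paw
(sd = `noise_sd` cmH2O) and flow (sd = `noise_sd`/10 L/s, a sensor-scale
equivalent; no flow-noise figure is standard) channels. Volume and the gold
Pmus channel stay noiseless — the gold channel is the answer key, and a
volume channel that integrated flow noise would random-walk ~0.3 L over 30 s.
Consequently the volume = ∫flow invariant is validated on noiseless exports.

## The scenario battery

49 scenarios: 6 per asynchrony category × 7 categories + 7 synchronous,
spanning the three mechanics presets — normal (R=10, C=50), obstructive
(R=20, C=60), restrictive (R=10, C=25); conventional teaching-range values,
recorded in the manifest — at two effort intensities each. Each is a 30-s
recording. Recipes construct each asynchrony mechanistically (weak efforts
against a high pressure trigger; artifacts with zero Pmus; a long strong
effort against a 0.4-s maximum inspiratory time; entrainment at fixed delay,
with amplitude deciding whether a second cycle stacks; a 0.5-s set
inspiratory time ending before the effort peak; a 1.5-s VCV inspiratory time
outlasting a 0.8-s effort). Recipe parameters were tuned during construction
until each scenario physically realizes its injected label under all three
presets — notably, restrictive mechanics equilibrate so fast that stacked
cycles only arise while Pmus is still *rising*, which shaped the
double-triggering and reverse-triggering-with-double-cycling recipes. A
minority of scenarios (the stacked-cycle and short-inspiration recipes)
necessarily exhibit a second asynchrony and carry it as a secondary label.
Composition is fully deterministic and pinned in `manifest.yaml`.

## Labeling rules and tolerances

Efforts are maximal runs of Pmus ≥ 0.5 cmH2O lasting ≥ 100 ms (onset = first
crossing, end = decay below threshold; the threshold is a display-resolution
choice). Breaths pair to efforts in two modes: *initiated* (trigger within
[onset − 0.1 s, end + 0.3 s]; nearest onset wins) or, failing that,
*entrained* (effort onset inside the breath's inspiration) — the second mode
is required for reverse triggering, where the machine trigger precedes the
effort. Rule order, first match per breath: ineffective effort (unpaired
effort), double triggering (≥ 2 initiated breaths within effort duration +
window), auto-triggering (patient/artifact trigger without effort), reverse
triggering (machine breaths whose entrained-effort delay is stable — sd
< 0.1 s over ≥ 3 consecutive machine breaths — with the double-cycling
variant when the effort also owns a stacked breath), premature cycling
(cycle-off before the effort peak), delayed cycling (cycle-off > 0.1 s after
the effort end), else synchronous. Trigger-phase rules precede cycling-phase
rules because they are defined on effort↔breath cardinality. A scenario's
label is the most frequent non-synchronous breath/effort label, ties broken
by rule order.

## Pmus estimation

With mechanics estimates, the model-based inversion is
P̂mus = R̂·V̇ + V·Ê + P̂0 − Paw, smoothed with a 50-ms centered moving
average, re-zeroed per breath on the median of its expiratory samples (a
breath with < 0.8 s of expiration — e.g. a stacked cycle whose expiration is
filled by the continuing effort — falls back to the record-wide expiratory
median), and floored at 0. Effort detection on an *estimated* channel uses a
250-ms minimum episode duration so brief inversion blips from circuit
artifacts are not read as efforts.

Mechanics identification has two routes. With known passive breaths: least
squares of Paw on (flow, volume, 1), after smoothing response and regressors
with the same 50-ms kernel — the relation is pointwise linear, so identical
smoothing preserves it exactly while averaging down the flow noise that would
otherwise attenuate R̂ (~2.5% at noise sd 0.5 cmH2O, brought below 1%).
Without passive breaths a plain or reweighted regression is fundamentally
unreliable: in a fully assisted record every inspiratory sample carries
effort, and the effort waveform is close enough to a linear function of
(flow, volume) that least squares absorbs it into the mechanics (observed
~30–45% understatement of both R and E with the time constant preserved).
The robust route therefore identifies the three parameters from structure
instead: P̂0 as the expiratory Paw median; τ̂ from the passive expiratory
manifold flow = −V/τ with iterative masking (effort makes flow + V/τ
strictly positive); and R̂ from the cycle-off jump — at the expiratory
switch Paw and flow jump together while volume and Pmus are continuous, so
R = ΔPaw/Δflow (the flow-interruption principle), pooled by median over
breaths; Ê = R̂/τ̂. On the battery this recovers R and C within ~3%
everywhere and the estimate tracks gold Pmus to ~0.1 cmH2O rms.

The recurrent estimator is a single-layer Elman network (32 tanh units,
linear readout floored at 0) mapping per-timestep (Paw, flow, volume) to
Pmus, trained with Adam on 3-s truncated-BPTT chunks of simulator output
(~3 s of CPU for 40 epochs on half the battery). It exists to demonstrate
that the effort waveform is learnable from airway signals alone; the split
is enforced at scenario level, training is deterministic given the seed, and
held-out error is ~1.6 cmH2O rms (≲ 0.5 cmH2O mean estimate on passive
records). The model-based route remains the primary estimator and nothing
else depends on the network.

## Trial statistics

Allocation is 1:1 within profession × experience strata using permuted
blocks of 2 (the smallest block keeping per-stratum imbalance ≤ 1).
Sensitivity is scored per participant as the fraction of asynchronous
scenarios answered with the key's exact primary label (per-type sensitivity
uses the same exact-match convention, since per-type reporting implies typed
scoring; the looser "any asynchrony reported" rate is computed alongside),
specificity as the fraction of synchronous scenarios called synchronous.
Group comparison is gated by Shapiro–Wilk at α = 0.05 per group: both normal
→ two-sample t (Welch by default; the pooled-variance classic form is behind
a flag), else Mann–Whitney; two identical constant samples compare at p = 1.
Sample size solves the smallest n with noncentral-t power ≥ target; the
design point (Δ = 10 pp, sd = 15 pp, power 0.90, α = 0.05 two-sided) gives
49 per group / 98 total, with power(49) = 0.904 and power(48) = 0.898. The
rater-response simulator draws per-scenario answers from per-type
sensitivity/specificity profiles with a configurable confusion distribution,
so the scoring and comparison pipeline is testable end to end without human
data.

## What the synthetic data does and does not show

The generator reproduces the *design* of the bench: stereotyped effort
pulses, clean single-compartment mechanics, idealized trigger/cycling logic,
and a gold Pmus channel. It does not model nonlinear or multi-compartment
mechanics, intrinsic-PEEP gas trapping, leaks, esophageal-pressure artifacts,
chaotic real-patient effort patterns, or the behavior of any specific
commercial ventilator or estimation algorithm. Passing the closed-loop tests
therefore shows the rules, estimator, and statistics are mutually consistent
and correctly implemented at bench realism — not that any of them is
clinically validated. Human-rater outcomes are measurements of people and
are out of scope as reproducible targets; the pipeline only demonstrates
that a between-group sensitivity difference of the designed magnitude is
detected with the designed power.

## Problem sizes

Default runs use 30-s records at 100 Hz (3000 samples), the 49-scenario
battery, 20 replicates for noisy mechanics recovery, 10,000 Monte-Carlo
replicates for power, and one 98-rater simulated trial; these sizes make the
full suite and the acceptance script run in well under a minute each while
leaving all statistical checks comfortably powered.
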