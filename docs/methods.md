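# Methods

## Task geometry and timing

The simulated trial is a paced trace of a three-cycle sine wave. Geometry
uses a top-left origin, x rightward, y downward, float pixels; the default
canvas is 1920 × 1080 px mapped onto a 309 × 174 mm plotting area (≈6.2
px/mm) at 60 Hz. The cycle period is fixed at 2 s: the pacing requires each
sine extremum to land on a beep at 1-s intervals, and extrema sit at
quarter-period offsets, so `period/2 = 1 s` exactly. Total movement time is
therefore 6 s, sampled at 361 frames including both endpoints.

The sine amplitude (270 px, a quarter of canvas height) and horizontal span
(10–90 % of canvas width) are not fixed by the task description; they were
chosen once as plausible screen-filling values and are exposed in the run
configuration. Start side (left or right) is encoded by the sign of the
horizontal span; scoring is direction-agnostic.

All intervals are closed-open `[a, b)`. The cursor-visibility schedule masks
`[0, period + lead)` and `[duration − tail, duration]` with lead = tail =
0.5 s by default, leaving the visible window exactly `[2.5 s, 5.5 s)`; a
sample at 2.5 s is visible, one at 5.5 s is not. The trial end point is the
single closed boundary (it belongs to the tail mask).

## Participant model

Horizontal pen progression is beep-locked — identical to the paced target —
so all modelled variability is vertical. The vertical tracing error follows
a discrete mean-reverting (Ornstein–Uhlenbeck-style) walk at the frame
interval Δ:

```
e(t+Δ) = e(t)·(1 − g·Δ·κ) + drift_mu·Δ + motor_noise_sigma·√Δ·η
```

with κ = 1 s⁻¹ so the gains read as per-second correction rates, and
`g = visual_gain` when visual feedback is currently useful, `proprio_gain`
otherwise. SELF trials use the visible-window flag (vision helps only while
the cursor is shown); FAKE trials use proprioceptive control throughout,
because a replayed cursor is never informative about the pen. This is the
simplest error process that yields the two empirical signatures the indices
are built to detect: SELF movement error below FAKE after baseline
subtraction, and a spread of pen-replay distances across FAKE trials.

Defaults (chosen once as a realistic regime, with units): `visual_gain` 0.9
/s, `proprio_gain` 0.05 /s, `motor_noise_sigma` 40 px·s^−1/2, `drift_mu`
0 px/s. Under these, unguided error grows to ~50–90 px over a trial while
visually guided error stabilizes near 25–30 px, and mean FAKE pen-cursor
distances centre near 60–70 px.

The practice pool holds 25 visually-guided trials, of which the last 20 are
eligible as FAKE replays (the first five are treated as unstable and
excluded). Practice trials are generated under the same masking schedule as
main trials, and the 16 main FAKE sources are drawn without replacement;
both choices are underdetermined by the task description and are recorded
here as the package's own. Replays are time-locked: no temporal offset or
resampling, so the pen-cursor distance reduces to the difference of the two
vertical error paths.

## Judgment rule

Each trial's 9-point judgment comes from a weighted cue-integration rule on
the trial's mean pen-cursor distance D:

```
latent = 9 − 8·[ w·min(D/τ, 1) + (1 − w)·(1 − β) ] + ε,  ε ~ N(0, σ_J)
J = clamp(round_half_up(latent), 1, 9)
```

`w` is the sensorimotor-cue weight, `β` the prior self-belief, and τ the
prediction-error tolerance — the distance at which the sensorimotor evidence
saturates toward "other". τ defaults to 400 px, the scale at which a
misattributing participant would plausibly have flipped to other-attribution;
σ_J defaults to 0.5 scale points. SELF trials feed D = 0 (pen and cursor are
identical by construction).

Two shipped archetypes differ only in the judgment parameters: `pb_like` /
`healthy_like` (w = 0.9, β = 0.6) and `pa_like` (w = 0.15, β = 0.9). They
are qualitative profiles, not fits to any individual: with `pa_like`, D
barely moves the latent, so judgments sit near the self pole regardless of
prediction error (high FAKE incorrect-response score, low |r|); with
`pb_like`, judgments track D (lower misattribution, moderate-to-high |r|).

## Scoring and association

Movement error is the unsigned vertical distance from the pen to the target
*line* (the curve y(x) at the pen's horizontal position, not the paced
point), averaged per cycle, with the cycle-1 mean subtracted — cycle 1 is
always fully masked, so it baselines unguided tracing in both conditions.
Prediction error averages the Euclidean pen-cursor distance over
cursor-visible samples only; masked samples carry no comparable feedback.
The incorrect-response score is `9 − mean(J)` (SELF) or `mean(J) − 1`
(FAKE); the two deviations are complementary (they sum to 8 for any judgment
list).

The association analysis is the Pearson correlation between D and J over a
session's 16 FAKE trials, with a two-tailed p from the t transform
(df = n − 2) and a magnitude label on |r| with closed-open bins at 0.5
(moderate), 0.7 (high) and 0.9 (very high); the bins are configurable. A
constant input raises a degenerate-variance error rather than returning a
silent 0 — a participant in the pure-prior limit genuinely has no defined
correlation, and the pipeline reports that as "undefined".

## Cue-integration fit

`CueIntegrationModel.fit()` recovers (w, β) from observed (D, J) pairs with
τ known, by exhaustive grid search (step 0.01 on each axis) minimizing
`Σ (J − latent(D; w, β))²` with the latent clamped to [1, 9]. The objective
deliberately does **not** round the prediction: the observations already
carry the report-scale rounding, and rounding the prediction as well makes
the objective a staircase whose least-squares minimizer is biased (in
simulation, recovered w ≈ 0.83 for a true 0.90). Against the continuous
latent, the report noise acts as dither over the rounding and the estimator
is unbiased in the designed regime (σ_J = 0.5). Exact ties resolve to the
median of the minimizing grid points. Because the objective is piecewise
constant in the data, the honest uncertainty summary is the near-optimal
plateau (grid cells within one squared scale point of the minimum), which
`summary()` reports alongside the estimates; with only 16 trials the plateau
is wide, and it narrows with n.

With no report noise, exact parameter identification is impossible — many
(w, β) pairs generate identical integer judgments — so tests assert
prediction equivalence there, not parameter equality.

## Problem sizes and determinism

The comparison experiment runs 200 sessions per profile and the recovery
experiment 100 replicates of 160 FAKE trials; both complete in seconds on
one CPU and give stable means at that size (the contrast orderings are
identical across independent seed blocks). Every random draw flows from a
single `numpy` `SeedSequence`, spawned in a fixed order into per-component
streams (pool, trial order, replay sources, trajectories, judgments), so a
(config, seed) pair reproduces a session byte-for-byte through
serialization.

## What the generator does and does not emulate

It emulates the experiment's structure (trial counts, masking, pacing,
replay pool, judgment scale) and the mechanisms the indices are designed to
expose. It does not emulate pen pressure, reaction or countdown behaviour,
temporal misalignment between pen and replay (replays are time-locked),
horizontal tracing error, fatigue or learning across trials, or any
individual's actual parameter values. Under the default noise regime the
absolute FAKE incorrect-response means of both archetypes are higher than
those observed in real patients (simulated replay discrepancies are smaller
than the several-hundred-pixel distances real participants produce), so
passing tests establish the *contrast and ordering* properties — low-w
profiles misattribute more and decouple judgments from prediction error; 
SELF < FAKE movement error — not absolute score levels. Clinical assessment
scores can ride along in `ParticipantProfile.label` as free text but are
never computed on.
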