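# Methods

## Scope

`m2afc` implements a complete analysis chain for premotor-cortex (M2)
single-unit recordings collected during a rodent two-alternative
forced-choice (2AFC) task, together with a synthetic session/spike generator
that provides ground truth for every stage.  The chain is: behavioral metric
extraction → single-unit task-relevance screening and side-preference
classification → session-normalized population PETHs with per-bin separation
inference → pseudo-population cue decoding against a label-shuffle null.

## Behavioral task model

A trial is a small state machine.  The animal self-initiates by breaking the
IR beam of a central well, holds the nosepoke for a uniformly drawn 200–700
ms period, and then one of two LED cues (left/right, Bernoulli 0.5) lights.
Leaving the well before cue onset is a *premature* trial (10 s timeout, no
cue or press timestamps).  The interval from cue onset to well exit is the
*decision time*; cue onset to lever press is the *reaction time*.  A press on
the cued lever is *correct* (5 s ITI); the wrong lever is *incorrect* (10 s
ITI); no press within the 5 s response window is an *omission* (10 s ITI;
omissions still have a well-exit time, so they contribute decision times but
no reaction time).

Per-session metrics: trials initiated; percent premature (of initiated);
accuracy = correct / cued, so omissions count against accuracy (the accuracy
deficit the analyses care about is omission-driven); percent omission and
percent incorrect (of cued; the three cued percentages sum to 100); lever
press index = ITI presses / (ITI + in-trial presses), a motor-output control
that rises when pressing moves outside trials; and median decision/reaction
times.  When no trial reached cue presentation the cued percentages are
reported as NaN, never as zero.

Group inference on per-subject summaries uses a two-way (sex × treatment)
OLS ANOVA via statsmodels with Sidak-adjusted within-sex treatment post
hocs.  A restricted-maximum-likelihood mixed model is deliberately out of
scope; with one summary row per subject × treatment the fixed-effects ANOVA
answers the same questions.  Latency-distribution variability is compared
with the Brown–Forsythe test (one-way ANOVA on absolute deviations from
group medians), which is robust to the strong right skew of latencies.

## Synthetic generator

`GeneratorConfig` holds all knobs; a single master seed fans out to
per-subject and per-unit children through `numpy.random.SeedSequence.spawn`,
so any subject or unit regenerates identically in isolation and fixed
(config, seed) reproduces files byte for byte.

Behavioral draws: uniform i.i.d. holds (the schedule is unspecified upstream;
uniform is the simplest faithful reading); log-normal decision times and
press latencies (right-skewed, positive support — medians are the natural
location parameter); exponential inter-initiation delays (`init_delay_mean`)
calibrated per group so full-length (2400 s) sessions reproduce the target
group means of trials initiated (≈144/53 female vehicle/propranolol, ≈128/81
male).  Outcome probabilities (`p_premature`, `p_omit`, `p_correct`) are
per-trial Bernoulli draws; ITI lever presses are Poisson at `iti_press_rate`.

Spike trains are inhomogeneous Poisson processes generated by thinning: a
homogeneous candidate process at the rate ceiling is kept with probability
rate(t)/ceiling.  For a task-locked unit, rate = baseline × `gain_preferred`
(default 2.5) from preferred-cue onset until the press (or until well exit +
response window on omissions), baseline × `gain_nonpreferred` (default 0.4 —
active inhibition) on nonpreferred-cue trials, plus a linear ramp of
`ramp_amplitude` over the final second before a preferred-side press.
Non-task units are homogeneous Poisson.  Baselines are log-normal across
units.  Task-locked assignment is deterministic (`frac_task_locked` of the
units, exactly) and preferences alternate left/right so small cohorts stay
balanced; generated units have matching cue and press preferences.

The treatment ("propranolol") condition applies two knobs:
`treatment_disinhibition` pulls the nonpreferred gain toward 1 (full
disinhibition in the female cell, 0.8 in the male cell), and
`treatment_rate_shift` adds to baselines (+1.11 Hz female, +0.13 Hz male,
matching the rate-distribution shifts the pipeline is meant to detect).
Per-cell behavioral overrides encode the 2×2 design: female propranolol has
~29% omissions and 1.19 s median decisions, male propranolol ~6.6% and
0.68 s, and so on.

What the generator does **not** emulate: within-session nonstationarity
(rates are stationary; no drift knob), inter-neuron correlations beyond
shared event-locked gain, biophysical spike dynamics (refractoriness,
bursting), electrode drift or sorting errors, and any within-session
pharmacokinetics.  Passing tests therefore demonstrate that the analysis
chain recovers known structure from idealized Poisson data — not that it is
robust to every artifact of real recordings.

## Screening and side preference

Units from sessions with fewer than 20 trials are excluded (logged, not
raised).  Four 1 s epochs are counted per unit with half-open [start, end)
windows: [0, +1) s after left and right cue onsets (cue epochs include
omitted trials) and [−1, 0) s before left and right presses (completed
trials only).  Each epoch's per-trial counts are paired with a 1 s window
centered in the *same trial's* following ITI, tested with a paired t
statistic on count differences, and Bonferroni-corrected over the family of
four.  A unit is task-locked if any adjusted p < α.  Epochs with fewer than
two pairs, or identically zero differences, are recorded as unavailable
(NaN) rather than fabricated.

The side preference index uses summed session counts per epoch:
SPI = (L − R)/(L + R), positive = left-preferring; L = R = 0 gives NaN and an
SPI of exactly 0 maps to "none" (such units are excluded from
preferred/nonpreferred splits; ties are otherwise undefined upstream).
Group-level unit statistics: mean rate ± SEM per cell, Mann–Whitney on rate
distributions (vehicle vs propranolol within sex), Fisher exact
(probability-mass two-sided convention) on task-locked and preference 2×2
tables.

## Population PETHs and separation

Each unit's firing is binned at 100 ms across the entire recording; the mean
μ and SD σ of the binned rate define z(r) = (r − μ)/σ.  Units with σ = 0
(silent or perfectly regular) are excluded.  Event-aligned windows are
[−1, +3] s around cue onset (all cued trials, omissions included) and
[−3, +1] s around the press (completed trials).  Each eligible unit
contributes two rows: mean z over preferred-side trials and over
nonpreferred-side trials, with the preference taken from the cue SPI for cue
alignment and the press SPI for press alignment (the two disagree for a
fraction of units, so each alignment uses its own label).

Separation is tested per bin with a paired t across units (preferred vs
nonpreferred row values), Holm–Sidak step-down corrected over **all bins in
the displayed window** (whether the original analyses restricted the family
to post-event bins is unstated; the full window is the conservative
choice).  Bins with zero variance of the paired differences get p = 1.  The
profile reports the per-bin masks, the longest contiguous significant run
(the headline duration), and the total significant time (reported because
"sustained for X s" is ambiguous between the two).

### Separation study calibration

The reference separation study (`studies.separation_study_config`) pools
task-locked, side-preferring units from three ~12-minute sessions (10 units
each, 70% task-locked) with median baselines of 1.25 Hz, gains 2.5/0.4, a
0.5 Hz ramp, and widened latency spreads (log-SD 0.8 decision / 0.9 press).
This regime was calibrated once so the vehicle-like population shows
sustained separation on the empirically relevant ~1.3–1.8 s scale.  The
calibration matters: on long, clean, high-rate sessions the paired tests
saturate — preferred excitation alone keeps every post-cue bin significant
for the entire press-time tail — and the separation duration becomes an
uninformative readout of the latency distribution.  Near the detection
threshold, removing active inhibition (gain_nonpreferred → 1, the
disinhibited variant) cuts the population contrast by the factor
(g_pref − 1)/(g_pref − g_nonpref) ≈ 0.71 and the longest run collapses by
more than half on matched seeds, reproducing the vehicle/propranolol
contrast the pipeline is designed to expose.

## Pseudo-population decoding

Decoding uses 150 ms bins over [−0.6, +1.5] s around cue onset (14 bins; the
window start and resample counts are not pinned upstream and are exposed as
configuration).  For each of 50 outer resamples, 10 units are drawn without
replacement and each contributes 10 independently drawn training trials per
cue side plus held-out test trials (units need not share a session;
pseudo-trial k deliberately pairs unrelated real trials).  Per bin, features
are the 10 units' counts, standardized by training-set mean/SD; a linear
SVM (unit cost) is trained and scored on the held-out pseudo-trials; a bin
whose training features are constant falls back to the majority class
(accuracy 0.5 by balanced design).  Accuracy is averaged over resamples.

Significance per bin comes from a permutation null: cue labels are shuffled
within each unit's sampled trials and the full resampled decode repeated (50
iterations), with the add-one estimator p = (1 + #null ≥ observed)/(1 + 50),
which cannot return p = 0 and has resolution 1/51 ≈ 0.0196.  Chance is
exactly 0.5 by balanced design.  The result carries the per-bin accuracies,
null distribution, p-values, significance mask, and the first significant
bin (onset).

## Statistics module

Bonferroni (`min(1, p·m)`) and Holm–Sidak (step-down, adjusted_(i) = running
max of 1 − (1 − p_(j))^(m−j+1), capped at 1; rejection stops at the first
failure) are implemented in-repo since per-bin families are the core
inference; both are pinned by closed-form and FWER-simulation tests, and
Holm–Sidak provably rejects a superset of Bonferroni at equal α.  Fisher
exact (probability-mass two-sided convention), Brown–Forsythe (Levene with
median centering), Mann–Whitney (tie-corrected), and the paired t are
delegated to scipy and pinned by enumeration/calibration oracles so the
backing implementation is swappable.

## Numerical and interface choices

- Counting windows are half-open [start, end): boundary spikes count once.
- All tables are comma-separated text with fixed float formatting; rerunning
  any stage with the same seed produces byte-identical files, and the
  pipeline log records per-stage seeds, settings, input digests, and
  inclusion/exclusion counts.
- Test and acceptance runs use reduced problem sizes (1 subject per cell,
  10–30 units, 12–40 min sessions, 3–20 resamples/shuffles) chosen so each
  property is measured at adequate power; generator defaults keep the
  full-scale study conditions.

## Known limitations

- The treatment condition only disinhibits nonpreferred responses and shifts
  baselines; preferred excitation is untouched.  On full-scale cohorts the
  preserved preferred signal keeps the treated population's separation
  statistically robust, so the vehicle-vs-treated duration contrast is only
  expressed in the calibrated near-threshold separation study, not in the
  default full-scale cohort.
- The generator's press preference always equals its cue preference, so the
  cue↔press consistency fraction is ~1 on synthetic data (real populations
  change preference for a sizable minority of units).
- No temporal-generalization decoding, no multiclass labels, no
  ramping-model fitting, and no LFP/waveform features.
- The behavioral ANOVA is fixed-effects on per-session summaries; designs
  with repeated sessions per subject would need a mixed model.
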