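# Methods

## Model structure

Each patient is simulated as an independent stock-and-flow system on a
yearly grid running from disease onset to the re-evaluation interview.
Twelve aggregate state variables (anxiety, depression, sleep inertia, work
and social impairment, sleepiness, fatigue, naps, nocturnal sleep, other
psychiatric disorders, somatic pathologies, methylphenidate effect,
modafinil effect) are levels driven by target-seeking balancing loops: the
level moves toward a time-varying goal g_t at a speed set by an adjustment
time d. The net rate law is

    raw_t = (g_t − PV_t) / d
    literal:    δIF_t = MIN(raw_t, g_t)
    symmetric:  δIF_t = sign(raw_t) · MIN(|raw_t|, |g_t|)   (g_t ≠ 0, else raw_t)

and the level accumulates δIF by explicit Euler with Δt = 1 year — the
model's native clock; no sub-stepping is used, so the delay d and the step
interact exactly as in the difference equation. The literal cap, applied
verbatim, makes a negative goal *repel* the level (MIN picks the more
negative of raw and g), which contradicts the balancing-loop reading in
which every level "gradually approaches" its goal. Both behaviors are
implemented; `symmetric` is the default and `literal` is retained for
fidelity experiments. Neither is asserted correct — the discrepancy is
intrinsic to the printed rate law.

With a constant goal, symmetric mode and d ≥ 1, the level follows the
closed form PV_t = g + (IV − g)(1 − 1/d)^t whenever the magnitude cap is
slack (|IV − g| ≤ d·|g| suffices); the test suite verifies this to 1e−9 and
checks all trajectories against an independent year-by-year replay oracle.

The patient's overall experience is a thirteenth level whose goal at step t
is the *sum* of the twelve aggregate values at t (so its scale is wider
than [−100, 100]), integrated with its own delay (default 1 year; the value
is not specified by the underlying study design, and 1 year keeps the
experience a one-step-lagged tracker of the symptom total).

## Dynamization and normalization

Interview parameters arrive in native units and are normalized to a common
[0, 100] magnitude: linear between the instrument's theoretical endpoints
for continuous scales (ESS 0–24, BDI-like 0–63, STAI-like 20–80, …), evenly
spaced categories for ordinal items (equivalent to the linear map over the
level indices), and {0, 100} for binary/nominal presence. Instrument ranges
are preferred over cohort-observed ranges so results do not depend on the
data set at hand; cohort ranges can be supplied through the registry where
an instrument has none. Values outside the declared scale are clamped with
a logged warning rather than rejected — interview data plausibly contains
mild out-of-range entries.

Polarity turns the magnitude into a signed target: `always_negative`
phenomena (depression, fatigue, …) can only depress the experience;
`data_dependent` ones (naps, nocturnal sleep length, medication effect)
take their sign from the patient's recorded perception. A dynamic parameter
is zero before its first occurrence year, starts at its normalized extreme
value, moves through its change events — piecewise-constant by default, a
linear ramp when the event's rate qualifier says so (the qualifier's units
are not defined by the source material, so it is interpreted as a
step/linear switch) — and returns to zero after its last occurrence year.
Medication targets equal the normalized perceived effect during
administration and decay to zero over a one-year post-discontinuation
window at half strength ("persists only a short while" is not quantified;
one simulation step is the smallest representable persistence).

Aggregate goals are the mean of the member parameters' targets, clamped to
[−100, 100]; mean is preferred over sum because it preserves the scale
bound without routinely saturating the clamp. Only parameters actually
present in a patient's record enter the mean — averaging in the structural
zeros of the full 71-parameter catalogue would dilute every aggregate by
its catalogue size rather than by what the patient reported. Nap-related
sleep inertia is a separate input parameter under the sleep-inertia
aggregate, not a modifier of the naps aggregate, so refreshing naps
followed by inertia contribute to both with opposite signs.

The registry (`src/ihsim/data/registry.yaml`) is editable data: of the 71
parameters, only two membership counts are fixed by the source study
(somatic pathologies: 24, naps: 6); the remaining assignments follow
clinical face validity and can be rearranged without code changes.
Aggregate delays are set by face validity too — fast-acting phenomena
(stimulants, naps, sleepiness, inertia: 1 y), intermediate (mood, fatigue,
nocturnal sleep: 2 y), slowly accruing (social impairment, somatic burden,
other psychiatric: 3 y); the original per-parameter values are unpublished.

## Fit statistic

The derivative is the first forward difference on the yearly grid — the
only estimator the 1-year step admits. Segments are classified decreasing /
constant / increasing with a constancy tolerance ε, default 1% of the
larger value range of the two series being compared: a small nonzero ε is
needed to distinguish visually-flat from analytically-rising segments, and
tying it to the range keeps the statistic invariant under positive affine
rescaling of either waveform. The per-patient fit is the percentage of
matching segment classes (half-up rounded to 0.1); the cohort fit pools all
segments before dividing (default), so it is the match fraction of the
concatenated segment lists, not a per-patient average — a patient with a
long disease contributes more segments. An unweighted per-patient mean is
available.

The nine reported-course templates are canonical stand-ins (the original
plots are unpublished): monotone worsening/improvement run linearly between
0 and −amplitude, plateaus break at mid-course, reversals are V-shapes with
the extreme at mid-course, oscillations are 4-year sinusoids (±10 slight,
±40 strong). Custom-drawn courses are (year, value) anchor lists linearly
interpolated to the yearly grid.

## Scenarios and statistics

* `baseline`: every patient, full disease duration.
* `last5`: the final five yearly samples of each trajectory; patients with
  duration < 5 years are excluded (the exclusion predicate is configurable;
  the default reproduces the "disease lasted only 1 year" exclusion).
* `medicated_only`: the last5 window, restricted to patients with
  methylphenidate or modafinil exposure overlapping it.

Scenario filters select patients and years; they never alter values. The
contribution of aggregate i in a scenario is 100·|s_i|/Σ_j|s_j| where s_i
sums the aggregate's level over all selected patients and years;
percentages are half-up rounded to one decimal and sum to 100 within
rounding. Scenario comparison uses a two-sided Mann–Whitney test per
aggregate on per-patient windowed sums (per-patient means optional); the
p-value is exact by enumeration when the pooled sample is tie-free and
n1·n2 ≤ 400, otherwise normal approximation with tie and continuity
corrections (the computation is delegated to scipy; the test suite checks
the exact branch against a hand-written full-enumeration oracle). The
medicated subset is compared against the full last5 group, medicated
patients included — the two samples are therefore not independent, which
matches the published table's framing but should be kept in mind when
reading the p-values. No multiple-testing correction is applied.

## Synthetic cohort generator

The generator emulates the *marginal* statistical structure of the study
cohort (n = 43): demographic and sleep variables are drawn from
piecewise-linear inverse CDFs through the published quantile anchors, with
the published threshold proportions inserted as extra knots so they hold
exactly in the continuous CDF — 24-h sleep {0→603, 0.214→660, 0.5→690.5,
1→1100} min (so P(>660) = 78.6%), ESS {0→6, 0.15→10, 0.5→15, 1→23} (so
P(>10) = 85%), MSLT latency {0→1, 0.5→5.2, 0.738→8, 1→15.9} min. IQR and
confidence-interval figures are treated as soft checks only; they would
over-constrain a piecewise-linear CDF. Comorbidities are independent
Bernoulli draws at the published frequencies; stimulant episodes fall in
the final five disease years at the published uptake (33/40); disease
duration is interview age minus onset age with resampling of onset ages
that would give durations under one year. Symptom severities, change
events and perception flags are drawn from plausible ranges chosen once
(e.g. nap refreshment positive with probability 0.55).

Marginals are sampled independently — no within-patient correlation
structure is published — so the generator reproduces univariate calibration
targets (medians within 1%, proportions within ~1.5 points at n = 10,000)
but not joint structure; passing tests demonstrate that the *pipeline*
behaves correctly under the study's marginal conditions, not that the model
fits real patients.

Report modes: `self_consistent` copies each patient's simulated experience
back as their report (pooled fit 100% by construction — the end-to-end
smoke configuration). `template_noisy` snaps the experience to the nearest
of the nine templates, where "nearest" maximizes derivative-sign agreement
— the statistic's own metric; when no template reaches 0.9 agreement the
patient "draws" the course (the blank-graph option), and the drawing is
taken as accurate so that the noise parameter is the sole source of
reporting infidelity. Each segment class is then corrupted independently
with probability `report_noise` (to one of the other two classes,
uniformly) and the reported series is rebuilt from the class sequence with
10-unit steps — large enough that the 1%-of-range tolerance never
reclassifies an intended rise or fall as flat. Expected pooled fit is
therefore ≈ base·(1 − noise); noise ≈ 0.25 places a 40-patient cohort in
the mid-70s.

## Problem sizes and numerics

The shipped tests run cohorts of 10–43 patients (the study's scale) for
behavioral checks and 2,000–10,000 patients for calibration recovery, with
fixed seeds throughout; trajectories are a few dozen yearly steps, so
everything is exact arithmetic apart from the Euler scheme itself.
Degenerate inputs are rejected early with named errors: zero-width scales,
unordered occurrence years, overlapping medication episodes, schedules not
covering the simulation window, empty scenario selections. Ties in the
Mann–Whitney samples switch the p-value to the corrected normal
approximation; midranks are used for U in either branch.

## Known limitations

* The rate-law ambiguity (literal vs symmetric MIN) is resolved by a
  default, not by evidence; conclusions sensitive to repelling negative
  targets should be checked under both modes.
* Aggregate delays and the 41 unpublished membership assignments are
  editorial; contribution rankings partly reflect these choices.
* The generator's independence assumption understates real comorbidity
  clustering; calibration holds marginally only.
* Reported courses are retrospective single answers; the package models the
  report as a waveform and cannot correct recall bias.
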