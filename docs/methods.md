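# Methods

## Problem setting

Congestive heart failure (CHF) is incurable; keeping the patient's
health-related quality of life stable is a first-order treatment goal.
Telemonitoring programmes collect a daily *feeling of health* (FOH)
self-report on a 5-point scale alongside wearable, manual-entry and ambient
measurements.  This package implements a complete pipeline for predicting
the daily FOH class from those measurements, with particular attention to
the two questions that dominate this setting in practice:

1. **Label schema.**  One study dialect asks "compared to yesterday"
   (Chiron-style), the other "compared to usual" (HeartMan-style), with the
   numeric scales running in opposite directions.  Comparable modeling
   requires harmonizing the former into the latter.
2. **Personalization.**  Patients differ in baselines and in how their
   physiology maps to their reported state, and the data are heavily
   missing.  The pipeline therefore separates global from personalized
   imputation, and population-level from person-aware evaluation.

The original clinical datasets are not deposited anywhere, so the package
ships a synthetic cohort generator with known ground truth.  Every
scientific claim the test suite makes is a *property* of the method
(recovery, ordering, invariance), never a reproduction of any particular
clinical number.

## Label model

Canonical classes are `worse < same < better` (5-point answers merged 1-2
and 4-5; the merge absorbs each dialect's scale direction).  The
yesterday-to-usual transformation operates on runs of consecutive reporting
days, left to right:

* worse/same/better-than-yesterday default to the same class relative to
  usual;
* a `worse` followed by `same` days propagates `worse` for at most five
  consecutive days, counting the trigger day; propagation halts at any
  non-`same` label, and a fresh extreme restarts the window;
* `worse` immediately followed by `better` (and vice versa) marks the
  second day as `same` — an immediate reversal reads as a return to
  baseline — and halts propagation without opening a new window;
* rules apply symmetrically for `better`; nothing propagates across
  reporting gaps; the output has exactly the input length.

Two rule interactions are genuinely underdetermined by the verbal rules and
are fixed here as explicit precedence choices: the reversal rule is checked
*before* propagation, and after a reversal the affected day does not itself
propagate.  An independently written two-pass oracle (mark reversals, then
propagate) is compared exhaustively against the scanning implementation on
all 3^n sequences up to length 6 and on all gap placements of length-3
sequences.

## Synthetic cohorts

Each patient carries a latent daily state in {worse, same, better} relative
to their usual condition, following a *sticky* Markov chain: the state
repeats with probability `state_persistence` (default 0.8) and is otherwise
redrawn from `state_probs`.  The stationary distribution of this chain is
`state_probs` itself.  Defaults `state_probs = (0.25, 0.5, 0.25)` keep
`same` the modal state while leaving enough worse/better runs for the
run-based transformation rules to act on; `report_prob = 0.8` reflects
imperfect but majority adherence.  These are design choices of the study
conditions, documented here, not estimates of any real cohort.

Channels have population mean, between-patient SD and within-patient SD
(split into a day level and a sample level), a per-day sampling frequency
(hourly for wearable/ambient streams, one manual entry per day for weight,
blood pressure, SpO2), and a signed effect: worse days shift heart rate,
weight, blood pressure, galvanic skin response upward and skin temperature,
SpO2, energy expenditure downward, better days the reverse, all scaled by
`effect_size`.  Activity is a per-sample class label (5 HeartMan classes, 3
Chiron classes) drawn from a per-patient time budget whose active share
shrinks on worse days; heart rate and energy expenditure samples receive
activity-dependent offsets.  `effect_mode="patient_specific"` draws an
independent random sign per patient and channel, which cancels the
population-level feature-label link while preserving the within-patient
one — the device used to demonstrate that subject-wise evaluation
collapses where personalized evaluation does not.

Chiron-dialect reports encode the day-over-day ordinal comparison of the
latent state (first day of a reporting run is `same`: there is no reported
yesterday); HeartMan-dialect reports encode the latent state directly.
Raw 5-point values split each extreme into its two grades uniformly.

Missingness is injected MCAR in two layers: per-channel day-level Bernoulli
dropout, and multi-day non-wear blocks that wipe all wearable channels at
once.  Every removed value is recorded, so imputation can be scored against
exact truth.  What the generator deliberately does *not* model: circadian
and seasonal structure, informative (state-dependent) dropout, raw
waveforms, and drift.  Passing tests therefore demonstrate that the
machinery behaves as designed under its stated assumptions — not that any
particular accuracy level transfers to clinical data.

## Features

One row per FOH report, anchored at a fixed evening entry time (20:00).
Windows: 3h/24h/week ending at the entry, the calendar day of the entry,
day-over-day differences with a 3-day look-back fallback, and 1-/4-day
deltas for manual entries (4-day deltas fall back to 5-7 days).  Statistics
are mean and SD (SD of fewer than two samples is missing, not zero).
Implausible values are removed first (HR < 40 bpm, SBP > 200 mmHg,
DBP < 40 mmHg; bounds inclusive, values at the limit are kept).

Derived features include the rate-pressure product (SBP x mean HR within
+-10 min of the blood-pressure entry), skin/air temperature and
GSR/humidity ratios, the Chiron "double product" (mean of SBP and DBP times
daily mean HR), per-activity channel statistics, pairwise activity-duration
ratios and heart-rate contrasts, and the heart-rate/energy-expenditure
ratio.  Personal ratios divide a value by the patient's study-period
aggregate of that column (mean for mean-type features, SD for SD-type); a
denominator indistinguishable from zero at the column's scale (below 1e-9
of the mean absolute value, as happens for difference features whose
per-patient mean is ~0 by construction) yields a missing ratio.

Feature names are namespaced `group.channel.window.stat[.pratio]`, and
every column is described by exactly one registry entry carrying a dialect
flag; entries flagged `both` are defined identically in the two dialects,
so the cross-dataset compatible feature set is literally a name
intersection.  The registry is this implementation's enumeration — about
190 HeartMan and 100 Chiron columns — and makes no claim of count parity
with any other enumeration of the same measurement space.

No feature for day *d* uses data after day *d* ends; the day-of-entry
window extends past the entry timestamp to the end of its calendar date,
which is the one documented exception (verified by a truncation test).

## Preprocessing

Columns whose missing fraction strictly exceeds a threshold are dropped
(0.6 is the customary wristband-dialect setting, 0.3 the chest-strap one).
Imputation is KNN (k=5) or chained equations (max_iter=10); features are
standardized by fit-scope mean/SD before KNN distance computation.  Global
scope fits one imputer on the fit rows; personalized scope fits one per
patient on that patient's fit rows, with two fallbacks: a patient-column
with no observed fit values gets the global mean, and a patient absent from
the fit rows entirely (a held-out subject) goes through the global imputer.
Inside evaluation, imputers are always fitted on training rows only — a
deliberate strictness choice, enforced by a byte-comparison test of the
fitted state with and without the test rows present.  Observed cells are
never altered.

The optional previous-day FOH feature is yesterday's canonical label when a
report exists for the previous calendar day and `same` otherwise
(including a patient's first report); it is one-hot encoded and, being
always complete, never enters imputation.

## Modeling and evaluation

Minority classes in the training partition are oversampled to the majority
count with SMOTE (interpolation toward one of k=5 nearest same-class
neighbours; the neighbourhood shrinks for classes smaller than k+1, and a
singleton class is left alone with a warning).  Synthetic rows are flagged
and exist only in the training copy.  The classifier is a random forest
with library-default parameters; the exact values in use are recorded in
`RF_PARAMETER_REGISTRY` because "default" drifts between library versions.
Labels are unordered categories.

Metrics are accuracy (correct / total) and one-vs-rest per-class F1 (the
harmonic mean of precision and recall) with the *macro* average as the
canonical aggregate, because equal class weighting is the point of using F1
here; a frequency-weighted variant is available behind a flag.  Imputation
variants are compared with Welch's unpaired t-test on fold-level scores;
identical degenerate samples report p = 1 with a warning.

Split schemes: random 10-fold CV; leave-one-subject-out (LOSO); and
leave-half-a-subject-out, a per-patient temporal split at the midpoint of
the patient's observed date span with ties to training (a patient observed
days 0-100 trains on 0-50), patients with fewer than two reports excluded
and logged.  A single global seed fans out to every stochastic stage, so a
full grid re-run is bit-reproducible.

### The negative-control null

With `effect_size = 0` the latent state leaves no trace in the channels,
yet a classifier can still beat naive chance under 10-fold CV: patients are
identifiable from their baselines, and under a persistent latent state each
patient's *label frequencies* deviate from the population's, so memorizing
a patient's majority label is a real — but day-level-information-free —
strategy.  The chance band for the negative control is therefore computed
by permuting labels *within patient*: that null preserves everything
patient identity alone can provide and destroys exactly the day-level
feature-label link the pipeline claims to detect.  The zero-signal check
asserts every scheme's macro F1 lies within 3 Monte-Carlo SDs of this band.

## Problem sizes

Recovery and gap experiments run at sizes chosen to keep the full suite
fast while leaving comfortable statistical margins: label-recovery cohorts
at 20 patients x 120 days over 10 seeds; value-recovery (imputation) and
personalization-gap cohorts at 10 patients x 60 days over 10 seeds, the
latter with the compact day-level feature registry; the feature oracle at 5
patients x 30 days with the full registries.  All sign-test assertions
reach p < 0.005 at 10/10 wins and still pass at 9/10.

## Known limitations

* MCAR missingness only; informative dropout would change the
  imputation-comparison conclusions and is out of scope.
* The latent state is 3-valued; 5-point severity grades are cosmetic
  (random splits), so nothing can be learned about distinguishing "much"
  from "somewhat".
* Chiron features are day-level by design; sub-daily windows are only
  enumerated for the HeartMan dialect.
* "Exercise validity" is a pass-through binary channel; no semantics are
  modeled for it.
* The transformation's propagation rules are a minimal-assumption reading
  of their verbal statement; the two documented precedence choices are
  choices, and alternates would change labels on a small fraction of
  days (the exhaustive oracle pins the implemented semantics exactly).
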