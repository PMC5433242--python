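# Methods

This note documents the models, rules and numerical choices behind
`eegprog`, and what the synthetic data can and cannot establish.

## EEG background classification

### Amplitude semantics

The clinical pattern definitions quantify amplitude ("<20 µV",
"activity <10 µV") without saying peak-to-peak versus half-amplitude.
All thresholds here are **peak-to-peak within a sliding 0.5-s window**:
`amplitude_envelope` computes max–min per channel with a centered
0.5-s window (edge-clamped), then takes the maximum across channels, so a
threshold applies to all channels jointly.  The cross-channel maximum is
the conservative reading of "low-voltage" — no channel may exceed the
bound.

### Segmentation rules

* **Suppression**: a maximal run of envelope < 10 µV lasting ≥ 1 s.
* **Burst**: a maximal run of envelope ≥ 10 µV whose extent, after eroding
  half the envelope window from each interior edge (the envelope dilates
  activity by about half a window per side), lasts ≥ 500 ms and whose
  waveform shows ≥ 3 phases.  Phases are counted as sign-alternating
  excursions beyond ±10 µV after mean removal, merging consecutive
  same-sign excursions (ties break toward fewer phases).
* **Identical bursts**: the mean Pearson correlation of the first 500 ms
  of consecutive bursts, onset-aligned with a ±25 ms lag search that
  maximizes |r| (keeping the sign, so inverted copies score −1).  A mean
  score ≥ 0.75 marks the burst-suppression epoch as "with identical
  bursts".  No numeric criterion for burst identity is published; 0.75 is
  this package's documented operationalization and is far above the
  scores independent bursts reach (|mean| < 0.3 empirically).
* **Dominant frequency**: peak of the channel-averaged Welch spectrum
  (4-s segments, 50% overlap) in 0.5–25 Hz.  Flat signals raise an error.

### Decision cascade

1. Artifact screen (>20% of samples beyond ±300 µV) → unassessable.  The
   additional dead-channel (zero-variance) rule applies only during epoch
   *selection*: a genuinely flat epoch is isoelectric, not artifact.
2. Envelope everywhere < 2 µV → isoelectric.  No clinical bound for
   "isoelectric" is published; 2 µV cleanly separates it from low-voltage.
3. Suppression fraction ≥ 10% of the epoch with ≥ 2 qualifying bursts →
   burst-suppression, split by the identical-burst score.  "Continuity"
   is not quantified clinically; < 10% suppression time counts as
   continuous.
4. Envelope everywhere < 20 µV → low-voltage.
5. Otherwise continuous: dominant frequency < 8 Hz → diffusely slowed,
   else normal.

Epileptiform activity (evolving seizures, GPDs) is **label-only**: the
cascade contains no spike detector by design, and simulated epileptiform
epochs are used only as labelled fixtures.

### Epoch selection

`select_epoch` mirrors the random epoch draw at 12/24 h after arrest:
uniform 5-minute candidates within ±1 h of the target, rejecting
artifact-dominated candidates (up to 20 tries), returning none when the
recording does not cover the window — which reproduces the dominant
missingness mechanism (monitoring started after 12 h).

## The EEG generator

`simulate_epoch` produces amplitude/frequency caricatures that satisfy
each category's defining thresholds by construction: uniform noise below
2 µV p-p (isoelectric); a 6-Hz rhythm at 14 µV p-p with mild amplitude
modulation, never dipping below 10 µV (low-voltage); alternating 2–4-s
suppressions (4 µV p-p) and 0.7–1.5-s bursts of 1–12 Hz band-limited
noise at ~120 µV p-p under a Tukey taper, with the identical variant
reusing one burst realization (sample-aligned, i.e. sub-millisecond
jitter); 4-Hz or 10-Hz dominant rhythms at 50 µV p-p (continuous slow /
normal); 2-Hz periodic stereotyped discharges (epileptiform, label-only).
Default: 256 Hz, one channel — the multi-electrode montage is irrelevant
to amplitude/frequency rules and one channel keeps fixtures small;
multi-channel epochs share the base signal plus independent noise floors.

What passing the round-trip test (≥95% label recovery over 50 seeds per
category) shows: the classifier's thresholds implement the written
definitions consistently.  What it does not show: performance on real
EEG, which has reactivity, artifacts, spatial structure and borderline
patterns (waxing-and-waning burst-suppression, sporadic >20 µV activity)
that drive the published interrater disagreements.

## The cohort generator

One patient is drawn as: outcome (poor with p = 197/388); for poor
patients, early death before 24 h (11/197); among survivors of day 1, a
24-h epoch is artifact-missing with p = 21/377, otherwise unfavorable
with p = 52/179 (poor) or 0 (good — hence specificity is structurally
100%); death given an unfavorable 24-h EEG has p = 51/52, given any other
poor course 115/134, reproducing 177 deaths among 197 poor outcomes in
expectation; surviving poor patients get CPC 3.  Monitoring start hours
are lognormal (median 6.8 h, log-SD 1.269, so P(start > 12 h) ≈ 127/388);
the 12-h epoch is favorable with p = 63/123 (good) or 15/125 (poor) when
assessable.  Within each prognostic group the category composition is not
published; fixed plausible splits are used (unfavorable: 25% isoelectric,
35% low-voltage, 40% identical-burst suppression; intermediate: 50/50
epileptiform / heterogeneous burst-suppression; favorable: 60/40
slowed / normal).

Stay durations are lognormal, moment-matched to the printed mean/SD and
the only published constraint (nonnegative, right-skewed): survivors draw
ICU ~ (8.2, 10.8) and GW ~ (9.6, 12.7) days.  For patients dying after
day 1 the **withdrawal day is primary**: lognormal (3.9, 1.8) days for
the unfavorable subgroup (chosen so the observed subgroup ICU mean ≈ 4.1)
and (4.6, 2.9) otherwise, truncated at 1.05 d; death follows after an
exponential residual with mean 0.2 d, chosen so the counterfactual
24-h-withdrawal subgroup mean is ≈ 1 + 0.2 days; ICU days equal
withdrawal + residual, and with probability 0.09 (deaths outside the ICU)
a zero-inflated lognormal GW tail (6.7, 12.0) is added, reproducing the
subgroup GW mean ≈ 0.6 with a large SD.  Consequences: the realized
whole-cohort mean ICU stay is below 8.2 d (deaths are tied to death
days), and the counterfactual subgroup means (≈1.2–1.6 ICU days at 24 h)
vary with the drawn unfavorable survivor — the generator reproduces the
published *conditional EEG probabilities* exactly in expectation, and the
economics qualitatively.

## Diagnostic accuracy

Exact Clopper–Pearson intervals (via the beta-quantile closed form) are
used throughout; the method is not named in the source material, and
exact intervals reproduce the checkable printed bounds (98 at 178/178,
100 at the upper boundary).  For 52/179 the exact lower bound rounds to
23% where 22% is printed — consistent with a Wald interval having been
used there; the exact choice is kept for determinism and boundary
correctness.  Zero-denominator metrics are flagged absent, never reported
as 0.  Display rounding is half-up to whole percents; raw proportions are
retained.  Cohen's κ uses the standard asymptotic variance.

## Cost model

Day convention: day 1 is the first 24 h after arrest; a decision "at
24 hours" means ICU occupancy through day 1 plus the preserved residual
interval, "at 72 hours" through day 3.  Fractional days are kept for
costing (cost = duration × day price, accumulated in integer cents); the
decision tree ceils durations to whole days, and its expected occupancy
(sum of cumulative branch-probability products) equals the mean of the
ceiled durations exactly — the two computation routes agree by
construction and are tested against each other.  In the withdrawal
pathways an EEG (€21) is charged for every patient alive at 24 h, and the
SSEP (€149) is not charged for patients whose unfavorable EEG alone
decides; patients with favorable, intermediate or unassessable 24-h EEG
follow current care, as do deaths before 24 h and the unfavorable-EEG
survivor (long-term mortality is unchanged by assumption of perfect
specificity).  Out-of-scope by design: societal costs (nursing homes,
rehabilitation, readmission) and quality-adjusted life years.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`).  The test suite uses 5-minute epochs at
256 Hz (50 seeds per category for classifier recovery), 200 default
cohorts for calibration recovery and 100 perturbed cohorts for the
scenario invariants; the acceptance script runs one 388-patient cohort
and 20 epochs per category.  These sizes give binomial standard errors
well inside the asserted bands while keeping a full run in seconds to a
few minutes.

## Known limitations

* Synthetic EEG lacks every nuisance that makes visual classification
  hard; classifier accuracy here is an upper bound.
* The joint distribution of 12-h and 24-h categories is modelled as
  conditionally independent given outcome; only the marginals are
  calibrated.
* Published per-patient cost *levels* are not reproduced — they depend on
  patient-level stay data that were never released — only the comparison
  structure (differences, reductions) is.
* EDF epochs can be read (optional `mne` extra) but not written; the
  native epoch format is plain CSV.
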