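# Methods

`wardalert` evaluates two ways of turning ward vital signs into deterioration
warnings — periodic early-warning scoring at nurse observations versus
continuous per-minute scoring of wearable-monitor streams — against
escalation-of-care (EOC) endpoints: rapid-response team (RRT) activation,
unplanned ICU admission, emergency surgery, or death.  Because the original
patient-level data are not publicly available, the pipeline runs on synthetic
cohorts that reproduce the cohort-level conditions of the study it models,
and the study's published contingency counts serve as an exact worked example
for the metric arithmetic.

## Time base and data model

All timestamps are integer minutes since admission (minute 0 = admission);
intervals are half-open `[start, end)`.  An admission couples three records:
per-minute vital samples (heart rate, respiratory rate, SpO2, systolic blood
pressure, skin temperature), periodic nurse observations (the same vitals
plus oxygen delivery and AVPU consciousness), and clinical events.  A missing
sample row means the monitor was offline that minute; a present row with an
empty channel means that sensor alone dropped out.  Exactly one terminal
censoring event (discharge or death) ends each admission.  Eligibility
(stay ≥ 24 h, monitoring connected within 12 h) is implemented as validation,
not as a hard filter, and applied once by the pipeline before scoring.

Sub-minute collapsing is out of scope: the one-row-per-minute convention is
asserted by this package, since the upstream device cadence already delivers
one vitals set per minute.

## Scoring

**Periodic scenario.**  A Modified Early Warning Score is computed at each
observation by summing per-channel band points plus oxygen-delivery and AVPU
add-ons; the alert threshold is 6.  The band table ships as configuration
(`config/mews_table.yaml`) and is a standard MEWS-style banding — a stand-in,
since the exact hospital-protocol bands behind the reference counts are not
public.  Bands are half-open, must tile the physiologic range of each
channel, and missing channels contribute zero points.

**Continuous scenario.**  Streams are first smoothed with a per-channel
running median over `[t − w, t + w]` (default half-window w = 5 min; the
existence of smoothing is part of the modelled system, its width is not
published).  The median replaces isolated faulty measurements with
surrounding reassuring data, never invents values outside the local range,
and leaves absent minutes absent.  Each smoothed minute then receives a score
on [0, 5]: with per-channel standardized deviations
`z_c = (x_c − center_c) / scale_c` over the four continuous channels (SpO2,
respiratory rate, heart rate, systolic pressure — skin temperature is
deliberately excluded because core temperature is not continuously measured),
the aggregate is the root-mean-square `r` of the `z_c` over *present*
channels, mapped by the saturating monotone function

    score = 5 · r / (r + 1.5)

A minute is valid only when at least 3 of the 4 channels are present (the
rule is applied after smoothing); the alert threshold is 3.  This scorer is a
documented stand-in for the proprietary index whose interface it reproduces
(0–5 range, ≥3-of-4 validity, threshold 3); no numerical fidelity to that
product is claimed.  With the default softness 1.5 an alert requires
`r ≥ 2.25`, i.e. an average deviation of roughly two scale units per channel.
The mapping is permutation-symmetric in the standardized deviations, so equal
deviations give equal scores regardless of which channel carries them or
which one channel is missing.

## Episode model

**Effective escalations.**  The first EOC-eligible event always counts.
After any effective escalation, only RRT activations at least 24 h
(1440 min) after the most recent effective escalation count as new
escalations; a non-RRT escalation closes the admission to further
escalations, and events after discharge or monitoring stop are ignored.

**Warning periods.**  An alerting score opens a warning period ending 4 h
(240 min) later; every further alert inside the open period extends the end
to 4 h past itself (greedy left-to-right chaining).  An alert exactly at the
period's end starts a new period — the half-open convention applied
uniformly.  A period that reaches an effective escalation is truncated there
and keeps the escalation on its closed right endpoint, because the
escalation results from the period; chaining resumes after the escalation.
Alerts after the final non-RRT escalation are discarded.

**Negative segments.**  The complement of the warning periods within
`[0, censor)` is cut into consecutive half-open blocks of at most 8 h
(480 min, the regular observation interval in stable patients) with one
shorter remainder per gap, so that both scenarios count comparable
evaluation units.  The cap is applied identically to both arms — the only
symmetric reading of the comparability rationale.  Censor time is the
earliest of monitoring stop, discharge, the final non-RRT escalation, and
the end of stay.

**Classification.**  Each effective escalation is matched to at most one
episode: the first warning period containing it (closed endpoint for
truncated periods), else the negative segment containing it (a terminal
escalation abutting the censor boundary is attributed to the last segment
via its closed end); an unmatched escalation would be a coverage error.
A warning period with a matched escalation is a true positive, otherwise a
false positive; unmatched escalations are false negatives; segments without
an escalation are true negatives.  `tp + fn` therefore equals the number of
effective escalations on every input, and warning periods plus negative
segments exactly tile the evaluable timeline.  Attribution is per period,
not per alert.  Lowering the continuous alert threshold can only enlarge
total warning time and never decreases the number of escalations covered.

The episode model is verified against an independently written brute-force
minute-sweep state machine on ≥1000 randomized alert/escalation
configurations; agreement is exact.

## Metrics

From episode counts: sensitivity `tp/(tp+fn)`, specificity `tn/(tn+fp)`,
PPV `tp/(tp+fp)`, NNE `= (tp+fp)/tp = 1/PPV` (exactly, pre-rounding), and
warnings per patient-day `(tp+fp)/patient_days` with patient-days summed as
stay length / 1440.  Proportion CIs are standard-error (Wald) intervals
`p ± 1.96·√(p(1−p)/n)` clipped to [0, 1]; the NNE interval inverts the PPV
interval endpoints.  Display rounding matches the reference presentation:
whole percentages, PPV to 3 decimals, NNE to the nearest integer,
warnings/day to 2 decimals.  Two published interval endpoints in the
continuous arm (PPV CI upper bound 0.009 and NNE CI 114–190) do not equal
the standard-error values computed from the printed counts; the worked
example therefore asserts all point estimates and only the reproducible
intervals.

**Lead time** is the time from a true-positive period's first alert to its
escalation, summarised by median and IQR; the cumulative detection curve at
x hours is the percentage of *all* effective escalations detected with lead
≤ x, so it is non-decreasing and plateaus at sensitivity × 100.  Quartiles
throughout use linear interpolation between order statistics (numpy's
default); the quartile convention of the reference analysis is not
published.

**Alert burden.**  The fraction of warning minutes is alerting valid minutes
divided by available valid scored minutes in a window — over the first 120
admission hours for the group contrast (escalation vs discharge without
escalation), and over the three 24-h bins preceding an escalation for the
prelude trend.  Admissions with no scored minute in a window are excluded
and counted.  Group contrasts use the Mann–Whitney U test with midranks and
the tie-corrected normal approximation,
`Z = (U − m·n/2)/sd`; when both groups have at most 8 observations the
exhaustive permutation p-value `P(|U − μ| ≥ |U_obs − μ|)` is returned
instead, because the normal approximation is unreliable at those sizes
(desk statistics packages switch the same way).

## Synthetic cohort generator

The generator defines the study conditions; its defaults are the cohort-level
rates of the modelled population:

| parameter | default | meaning |
|---|---|---|
| `eoc_fraction` | 0.07 | admissions ending in an escalation |
| `availability` | 0.79 | probability a monitorable minute is recorded |
| `discontinuation_fraction` | 0.11 | admissions whose monitoring stops early |
| `los_median_h` | 120 | median stay (log-normal, log-sd 0.6) |
| `obs_interval_h` | 8 | nurse-observation interval (jitter ±1 h) |
| `deterioration_onset_h` | 24 | mean onset of pre-escalation drift (sd 8 h) |

Stays are log-normal, clipped below at 26 h so that default cohorts satisfy
the ≥24 h eligibility rule — the generator emulates the post-exclusion
eligible cohort.  Each channel follows a stationary AR(1) process
(autocorrelation 0.97 per minute) around a patient-specific baseline;
minute-scale autocorrelation is required for the smoothing filter to be
meaningfully testable.  Escalating admissions acquire a linear drift toward
a per-channel terminal shift (+35 bpm heart rate, +8 /min respiratory rate,
−8 % SpO2, −25 mmHg systolic, −0.8 °C skin temperature) over the onset
window — the hypoxemia/tachycardia/hypotension pattern reported before ward
escalations.  Non-RRT escalations end the stay at the event; RRT calls occur
mid-stay (with a 15% chance of a second call ≥24 h later on long stays) and
vitals revert after the call.  All admissions additionally receive occasional
transient instability episodes (0.15/day, 2–6 h, one or two channels,
smooth raised-cosine shape) and rare 1–3-minute spike artifacts
(0.002/min) for the smoother to remove.  Missing data arrive in contiguous
geometric bursts (mean gap 30 min) via an alternating-renewal on/off process
whose long-run on-fraction equals `availability`, plus per-sensor dropout
bursts (3% of minutes per channel) so the ≥3-of-4 validity rule is
exercised.  The escalation-kind mix is uniform over the four kinds.

No quantitative description of real pre-escalation trajectories is available
for this population: the drift magnitudes, noise levels, episode rates and
artifact rates are placeholders chosen to be physiologically plausible, not
fitted values.  Passing tests on these cohorts demonstrate that the pipeline
machinery is correct and that the qualitative contrasts (earlier detection
and higher alert burden before escalation) emerge when gradual deterioration
is present — they say nothing about the numerical performance of either
score on real patients, and patient-level published results (median lead
times, burden medians, the published U statistic) are deliberately not
reproduction targets.

## Numerical and design choices

* Determinism: one `numpy` generator seeded per run drives the whole cohort;
  identical seeds give byte-identical cohorts and reports.  The pipeline
  hashes its configuration (output location excluded) into the run log.
* The ward is encoded in the admission-id prefix (M/S) because the on-disk
  schema has no ward column; the write→read round trip is field-exact.
* Degenerate inputs: an all-alert or no-alert cohort is reported with the
  undefined metric named rather than raised through the pipeline; an
  escalation at the censor boundary is attributed via closed endpoints;
  zero-length truncated periods are legal and classify normally.
* Episode/evaluation unit totals are a documented convention of this
  package; the reference study's raw evaluation-unit totals cannot be
  reconstructed from its published rules alone, so only its metric
  arithmetic from the printed counts is claimed.

## Problem sizes

The default analysis scripts use a 300-admission cohort; the parameter
recovery check and the acceptance script use 2000 admissions (about
10 million monitored minutes), sizes at which the empirical rates are
expected within 2–3 percentage points of their parameters.

## Known limitations

Physiology is not mechanistic: channels drift independently, there are no
circadian rhythms, interventions, or treatment responses, and observation
values are noisy re-reads of the latent state rather than nurse-validated
device readings.  The continuous scorer is an interface-compatible stand-in,
so absolute sensitivities/PPVs on synthetic cohorts differ from the
published ones by construction.  The MEWS banding cannot claim fidelity to
the specific hospital protocol.  Multi-ward transfers, waveform data and
real device ingestion are out of scope.
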