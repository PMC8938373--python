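# nbackerp

Working-memory n-back EEG/ERP analysis for two-group developmental cohorts,
with a synthetic-data generator that makes every stage testable against known
ground truth.

## The problem

In studies of working memory in pediatric clinical populations (the motivating
case is neurofibromatosis type 1 vs. age/sex-matched controls, ~16 children per
group, ages 11–17), behavior is measured with adaptive n-back staircases and a
Corsi blocks task, and cortical function with the P300 event-related potential
elicited by a fixed-order visual n-back task during 64-channel EEG. The raw
EEG of such studies is rarely public, so this package pairs the full analysis
chain with a generator that emulates the study's data structure — cohort
tables, behavioral sessions, and continuous recordings with a parietal P300,
ocular artifacts, and bad channels — allowing parameter-recovery validation of
the entire pipeline.

It is a library first (import `nbackerp`, see `examples/`), with a thin
`nbackerp` CLI over the stage pipeline for shell use.

## What it computes

* **Task engine** — adaptive staircase (level +1 at ≥90% block accuracy, −1 at
  ≤70%, stop after two consecutive blocks at an unchanged level; *mean n-back*
  = mean level over administered blocks), fixed EEG sequences (100 trials, 25
  targets, no cross-level accidental targets, 17 ms onset-jitter grid), block
  scores (hits/targets for the staircase; hits − false alarms, in percentage
  points, for the EEG task), Corsi span (mean of the two longest correct
  sequences).
* **Preprocessing** — averaged-mastoid re-reference, polyphase down-sampling
  to 200 Hz, zero-phase Butterworth filters (0.1 Hz high-pass, 48–52 Hz
  notch), epoching −600..1400 ms with −100..0 ms baseline; for ERP
  measurement: crop to −100..900 ms, 30 Hz low-pass.
* **Ocular-artifact removal** — 32 ICA components from the 64 EEG channels;
  per-component correlations with VEOG, HEOG (1–20 Hz band) and the average
  blink topography (50–250 ms blink-locked mean); each correlation set
  z-scored **across components**; suspects at |z| > 2, removed if the raw
  |r| > 0.2; removal projection composed with inverse-distance bad-channel
  interpolation into one cleaning matrix.
* **P300 measures** — ±120 µV artifact rejection, incorrect-trial rejection,
  temporal-proximity balancing of non-targets, window-mean amplitude and 50%
  fractional-area latency (FAL) at Pz in 300–700 ms, early/late split
  (300–500 / 500–700 ms) over four 7-channel ROIs (left/right ×
  frontal/parietal).
* **Statistics** — mixed factorial ANCOVA with age covariate and a
  homogeneity-of-regression gate (Type III via within-contrast GLM; for 1-df
  effects η²ₚ = F/(F + df₂)); pooled t and χ² group comparisons; Fisher
  r-to-z comparison of per-group Pearson correlations with Benjamini–Hochberg
  FDR (q = 0.10); linear-vs-quadratic comparison by AICc with evidence
  p = exp((AICc_q − AICc_l)/2); Kaplan–Meier curves and the log-rank test on
  achieved mean n-back.

## Worked example

`python examples/06_statistics.py` simulates a 16-per-group cohort, measures
each subject's P300 at 40 trials per condition, and runs the statistics layer:

```
== amplitude_uV ==  (homogeneity p=0.411, covariate kept)
  group        F(1,29) =  2.399, p = 0.1323, eta_p^2 = 0.076
  age          F(1,29) =  0.089, p = 0.7677, eta_p^2 = 0.003
  nback        F(1,29) = 43.670, p = 0.0000, eta_p^2 = 0.601
  group:nback  F(1,29) =  1.878, p = 0.1811, eta_p^2 = 0.061
  age:nback    F(1,29) =  0.654, p = 0.4251, eta_p^2 = 0.022
== latency_ms ==  (homogeneity p=0.025, covariate dropped)
  group        F(1,30) =  3.132, p = 0.0869, eta_p^2 = 0.095
  nback        F(1,30) =  1.136, p = 0.2950, eta_p^2 = 0.036
  group:nback  F(1,30) =  6.253, p = 0.0181, eta_p^2 = 0.172

2-back group latency contrast: diff = 41.5 ms, t(30) = 2.22, p = 0.0344
log-rank on mean n-back: chi2 = 20.54, p = 5.8e-06
```

Read: amplitude drops with memory load (the `nback` main effect) with no group
difference, while latency shows a group × load interaction — the clinical
group's P300 is earlier, specifically at 2-back — and behavioral capacity
(mean n-back) separates the groups strongly. That is the generator's injected
structure being recovered by the measurement and statistics layers. The
latency ANCOVA tripped its homogeneity-of-regression gate on this draw, so it
was refit without the covariate and flagged.

The other examples each exercise one capability (staircase, sequence design,
preprocessing round trip, ICA cleaning, P300 measurement, full pipeline); each
prints its numbers with a line on what they mean.

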