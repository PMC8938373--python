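# Methods

## Scope and shape

`nbackerp` implements a complete two-group working-memory ERP analysis — task
logic, EEG conditioning, ICA ocular-artifact removal, P300 measurement, and
the group statistics — together with a synthetic-data generator. The
generator is first-class code: it defines the conditions under which the
pipeline is validated, and all acceptance-style checks are parameter-recovery
exercises on its output. Nothing in the package depends on access to real
recordings, though BDF import is provided for them.

## The task models

**Adaptive staircase.** Block accuracy is hits/targets (no response is
required on non-targets, so false alarms do not enter the staircase decision;
a config switch exists to include them). Level moves +1 at ≥0.90, −1 at
≤0.70, floored at 1 and capped at 9; the session ends after the second
consecutive block *played* at an unchanged level (the counter resets whenever
the level moves), or at 20 blocks. Mean n-back averages over all administered
blocks, including the terminal pair. Each block has `level` lead-in screens
plus 20 critical screens with exactly 6 targets; lead-in screens are never
targets.

**Fixed EEG sequences.** 100 trials, exactly 25 targets. The cross-level
exclusion (no 1-back repeats in 2-back blocks, no 2-back matches in 1-back
blocks) is enforced during symbol assignment; a consequence worth noting is
that consecutive targets are impossible in 1-back blocks (a 1-back target
following another would create a 2-back match), so target placement there
samples uniformly from non-adjacent sets (a stars-and-bars construction —
rejection sampling is hopeless at that density), while 2-back blocks cap
consecutive-target pairs at 6. Onset jitter is k·17 ms, |k| ≤ 5. The letter
alphabet defaults to the eight consonants c, g, h, k, p, q, t, w; the
4-locus visuospatial variant is represented by four abstract symbols.

**Observers.** The adaptive task is driven by a capacity-limited observer:
hit probability `0.98 / (1 + exp((level − capacity)/0.35))`, 2% false alarms,
RTs Gaussian around 450 + 60·level ms. The staircase then converges near the
observer's capacity. The fixed EEG task deliberately does not push
performance to its limit, so it uses a separate observer anchored at ~87%
(1-back) and ~67% (2-back) hit rate with a mild capacity modulation
(0.03/unit) — both groups keep enough correct trials for ERP averaging, which
is the design intent of a fixed-order task.

## The synthetic EEG

A recording is the sum of:

* **Background**: 1/f ("pink") noise carried by 20 smooth random spatial
  fields (geodesic Gaussians, σ = 0.6 rad) plus an independent per-channel
  sensor-noise share (45% of the RMS), totalling 15 µV RMS per channel, and a
  shared posterior 10 Hz alpha source (4 µV RMS, weighted around POz).
  Spatially correlated background matters: volume-conducted EEG noise is
  correlated across neighbouring electrodes, and fully independent channel
  noise would make peak-channel identification unrealistically hard.
* **P300**: one Gaussian pulse per stimulus (σ = 70 ms) centred at the
  subject's true latency for that load level, spatially weighted by a
  geodesic Gaussian around Pz (σ = 0.5 rad, a focal mid-parietal topography).
  Ground-truth amplitudes are *window-mean* quantities (what the field
  reports); the injected peak is amplitude / 0.437, the window mean of a
  unit-peak pulse centred in the 300–700 ms window. Non-targets get 35% of
  the target amplitude; single-trial amplitudes jitter ±12%.
* **Artifacts**: Poisson blinks (subject rate 6–18/min, 200 µV Gaussian
  pulses, σ = 60 ms, minimum 400 ms gap) mirrored in VEOG and projected to
  the scalp with a frontal geodesic Gaussian (σ = 0.55 rad, gain 0.6);
  saccade steps (±35 µV, 0.2–0.6 s) in HEOG; optional bad channels replaced
  by 120 µV white noise. TP7 and a few other non-ROI channels are the
  candidate bad channels (Poisson(0.6) per subject, ≤3).

All randomness flows from a single `numpy.random.SeedSequence` with named
sub-streams (demographics / scores / ERP / artifacts at the cohort level;
responses / background / alpha / trial jitter / blinks / saccades / bad
channels at the recording level), so regeneration under the same seed is
bit-identical.

### Effect-size defaults and calibration

Cohort behavioral scores are Gaussian with the study's printed group
means/SDs (Conners, Vineland, digit span, TEA-Ch). Mean n-back and Corsi
means are not printed; the defaults (visual mean n-back 3.1 ± 0.8 control vs
1.9 ± 0.6 clinical, auditory 3.0/1.8, Corsi 5.3 ± 0.9 vs 4.5 ± 0.9) were
chosen once as values consistent with the strongly separated capacity
distributions the behavioral results imply.

ERP defaults are the printed results: Pz window amplitude 14.0 µV (1-back)
vs 11.5 µV (2-back); control latency 512 ms (1-back) + 21.7 ms load shift;
clinical-group shifts −20.4 ms (1-back) and −54.9 ms (2-back). Between-
subject variability is split into a subject intercept and a condition-
specific part and calibrated so that the **measured** statistics (after
40-trial averaging, which contributes ~1.2 µV amplitude and ~6 ms latency
measurement noise, the printed trial counts being ~39 per condition) match
the printed standard errors: amplitude intercept 5.1 / condition 1.9 µV,
latency intercept 39 / condition 23 ms. The printed spreads include
measurement noise, so the latent SDs are deliberately smaller than the
printed ones. Under these conditions the measured group contrast at 2-back
runs at mean |t| ≈ 3.3 across replicates — the same order as the study's own
reported contrast — and the detection power of the injected effects is ≈0.87
(latency) and ≈0.93 (amplitude) at α = 0.05, estimated from 300 replicates.

## Preprocessing choices

Filters are zero-phase (forward–backward) Butterworth, order 4 for the
pipeline high/low-pass and band-stop (the literature names cutoffs only).
Stage order defaults to re-reference → resample → filter, configurable. A
low-pass or notch at/above the post-resampling Nyquist (e.g. 120 Hz at
200 Hz) is skipped with a log note — the polyphase resampler already
anti-aliases. Windows are half-open [start, end) on the sample grid with
t = 0 at the stimulus-onset sample; *measurement* windows (300–700 ms etc.)
are inclusive of both endpoint samples, a 2 ms edge choice at 200 Hz. Units
are µV throughout; BDF import converts at ingest.

## Artifact identification

ICA is fit on the valid epochs' 64 EEG channels (continuous fitting is
possible by passing a recording), PCA-reduced to 32 components, unmixed with
FastICA, and ordered by explained channel-space variance. The scoring
procedure z-scores each correlation set (VEOG temporal, HEOG temporal, blink
spatial) across the component dimension, so a score indexes how unusual a
component's artifact correlation is relative to its peers; suspects have any
|z| > 2. Because a z outlier can occur in a tight correlation distribution,
a suspect is removed only if its raw |r| also exceeds 0.2; an operator
override hook replaces the selection and is logged.

Blink detection conditions VEOG with an order-2 zero-phase 1–15 Hz band-pass
and thresholds at median + 5·MAD with a 300 ms refractory period. The gentle
filter order matters: a steeper zero-phase high-pass leaves each blink
flanked by rebound shoulders (~16% of peak) that double-count blinks. As a
second guard, a candidate peak within 1.2 s of a >3×-larger accepted peak is
discarded — genuine consecutive blinks have comparable heights and survive.
A flat VEOG (zero MAD) yields no events and the spatial score is skipped
with a note.

Bad channels are flagged by robust variance z (median/MAD across channels,
threshold 4) plus a force-list for electrodes known bad from the recording
log. Interpolation uses inverse great-circle-distance weights over the 6
nearest good channels, normalized to sum to 1. The removal projection
I − A_r W_r is idempotent and leaves the orthogonal complement untouched;
the composed matrix (interpolation · removal) is applied once to the epochs.

## P300 measurement

Rejection: any |value| > 120 µV on an EEG channel, or an incorrect trial.
Balancing: per block, each valid target claims the nearest unclaimed valid
non-target by trial-index distance, ties to the earlier trial — never more
non-targets than targets. Fractional-area latency rectifies negative values
to zero before accumulating area (the P300 is a positivity; with signed area
the 50% crossing need not be monotone in time — a signed mode exists behind
a flag), integrates trapezoidally on the sample grid, and locates the
crossing by inverting the quadratic cumulative of the containing segment.
Zero rectified area raises a flagged error and the value is excluded from
statistics. A known property of FAL on noisy averages: rectified noise adds
a uniform area pedestal that pulls latencies toward the window centre
(measured chain slope ≈ 0.94) — an attenuation the measured study values
share, so no compensation is applied. Conditions with < 10 valid trials are
flagged low-trial.

## Statistics

With every within-subject factor at two levels, each within effect is a 1-df
contrast, so the mixed factorial AN(C)OVA decomposes exactly: each effect's
Type III F is the squared Wald t of the matching term in an OLS of the
per-subject contrast scores on [1, group (sum-coded ±1), mean-centred
covariate], with df₂ = n − p. This reproduces the standard
repeated-measures ANCOVA (cross-checked against an independent
implementation in the tests) and keeps η²ₚ = F/(F + df₂) exact for every
reported effect. The homogeneity-of-regression gate pre-tests the
group × covariate term on the subject means at α = 0.05 and refits without
the covariate (flagged) on violation. Sphericity is moot — all within
factors have 1 df.

Between-group correlation comparison uses Fisher r-to-z with
SE = √(1/(n₁−3) + 1/(n₂−3)); |r| at the ±1 boundary is flagged
non-computable. BH-FDR is canonical step-up at q = 0.10, applied within
each behavioral measure's set of correlations. (Canonical BH cannot
reproduce every published star pattern for this procedure — a p = .049 can
fail while a .022 survives only under a different grouping of the tests;
the implementation follows the canonical procedure.) The AICc is
n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k counting intercept, slopes and
scale (3 linear, 4 quadratic; constants cancel in the difference), and the
quadratic-vs-linear evidence p is exp((AICc_q − AICc_l)/2), floored RSS
guarding noiseless fits (which then resolve to the penalty difference,
flagged "linear preferred"). The Kaplan–Meier/log-rank analysis treats a
larger achieved mean n-back as longer survival with no censoring, since
every session reaches a terminal level. Follow-up simple-effect t-tests are
unpaired between groups and paired within group, uncorrected by default with
a corrected mode behind a flag.

## Problem sizes

The test suite and acceptance script run everything at sizes chosen for the
properties they check: sequence-count checks over 300–1000 seeds; the
end-to-end ICA cleaning property on one subject with two 60-trial blocks;
the pipeline smoke test at 4 subjects/group with two 30-trial blocks; and
parameter recovery at the study's full size (16/group, 40 trials/condition)
over 50 replicates, at the measurement level — per-subject trial-averaged Pz
waveforms are synthesized directly from ground truth plus averaged noise and
measured with the ERP layer, which is the quantity the statistics consume.
The continuous-EEG → ICA path is validated once end-to-end rather than
inside the replicate loop.

## Known limitations

* No biophysical forward model: topographies are geodesic Gaussians, not
  lead fields; source-level claims are out of scope.
* Only ocular artifacts and bad channels are modelled; no EMG, cardiac or
  line-noise transients (a 50 Hz probe exists only as a filter fixture).
* The generator's measurement-noise level is calibrated to trial counts and
  printed standard errors, not to any empirical noise spectrum; passing
  recovery tests show the chain is unbiased and adequately powered under
  these conditions, not that it would be under arbitrarily worse recordings.
* Fractional-area latency is the only latency estimator (no peak or
  50%-peak latency, no jackknife), and scalp statistics are ROI-based — no
  cluster-based permutation tests.
* BDF files can be imported but not written (no EDF/BDF writer dependency);
  the native container is HDF5.
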