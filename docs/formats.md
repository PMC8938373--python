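# File formats and conventions

Conventions used everywhere: sample indices are 0-based; times are
milliseconds relative to stimulus onset (t = 0 at the onset sample);
amplitudes are microvolts.

## Tables

* **Events / trials — TSV** (`events_<subject>.tsv`, `behavioral.tsv`,
  `cleaning_report.tsv`): one row per trial or per subject-session. Trial
  columns: `sample`, `onset_ms`, `block`, `level`, `position`, `stimulus`,
  `is_target`, `response`, `correct`, `rt_ms`.
* **Tidy results — CSV** (`subjects.csv`, `ground_truth.csv`, `measures.csv`,
  `stats_results.csv`, `correlations.csv`, `trial_counts.csv`).
  `measures.csv` has one row per subject × condition × window × site:
  `subject, group, condition, window, site, amplitude_uV, latency_ms,
  n_trials, low_trial`; `latency_ms` is present only for the full window at
  Pz and NaN when undefined.

## Array containers — HDF5

`nbackerp.containers.save_container` / `load_container` store the
array-bearing objects (`ContinuousRecording`, `EpochSet`, `ICAModel`,
`CleaningMontage`, `Evoked`) in a single HDF5 file per object:

* file attributes: `container_version` (currently 1), `kind` (the type
  name), `metadata` (JSON: rates, channel names, scalars);
* datasets: the numeric arrays under their field names; embedded tables
  (events, trial metadata) as JSON-with-schema strings so dtypes round-trip.

Write-then-read returns a structurally identical object with bit-identical
arrays. Missing blocks, truncated files and version mismatches raise
`ContainerError` naming the problem.

## Configuration — YAML

`RunConfig` round-trips losslessly through YAML (`config.yaml` in every run
directory); unknown keys are rejected at load time. Every stage marker and
the stats report embed the config hash and seed, so two runs with equal
configurations produce equal outputs.

## External formats

BioSemi BDF recordings can be imported (`containers.import_bdf`), with
volt → microvolt conversion at ingest. There is no BDF/EDF writer.
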