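"""Ocular-artifact removal: ICA component scoring and the cleaning montage.

32 components are extracted from the 64 EEG channels; each is correlated with
VEOG, HEOG and the subject's average blink topography; the correlations are
z-scored ACROSS components so a score says how unusual a component is, not
how big its correlation is.  Suspects (|z| > 2) whose raw |correlation|
clears 0.2 are projected out, together with bad-channel interpolation, in a
single composed matrix.
"""

import numpy as np

from nbackerp import ica, preprocess as pp
from nbackerp.montage import make_montage
from nbackerp.simulate import NoiseConfig, simulate_cohort, simulate_recording
from nbackerp.task import EEGSequenceConfig, generate_sequence

montage = make_montage()
_, gt = simulate_cohort(2, seed=21)
row = dict(gt.iloc[0])
row["blink_rate_per_min"] = 14.0

cfg = EEGSequenceConfig(n_trials=50, n_targets=12)
seqs = [generate_sequence(1, "eeg", cfg, seed=1), generate_sequence(2, "eeg", cfg, seed=2)]
rec = simulate_recording(row, seqs, montage, NoiseConfig(), seed=33)
rec = pp.rereference(rec)
rec = pp.filter_resample(rec)
epochs = pp.epoch_baseline(rec, (-600.0, 1400.0), (-100.0, 0.0))

model = ica.fit_ica(epochs, n_components=32, seed=0)
blinks = ica.detect_blinks_and_topography(rec)
print(f"{len(blinks.events)} blinks detected on VEOG "
      f"(true rate {row['blink_rate_per_min']:.0f}/min)")

veog = ica._epochs_to_matrix(epochs, ["VEOG"])[0]
heog = ica._epochs_to_matrix(epochs, ["HEOG"])[0]
ica.score_components(model, veog, heog, blinks.topography, epochs.sfreq)
removed = ica.select_removal(model)
for k in removed:
    print(f"component {k}: z_veog={model.zscores['veog'][k]:+.2f}, "
          f"z_blink={model.zscores['blink'][k]:+.2f}, "
          f"raw r_veog={model.corr['veog'][k]:+.2f}  -> removed")
print(f"suspects: {int(model.suspects.sum())}, removed: {removed}")

bad = ica.detect_bad_channels(epochs, force=("TP7",))
cm = ica.build_cleaning_montage(model, removed, montage, bad)
print(f"bad channels interpolated: {bad}")
print("# the composed matrix (interpolation @ removal) is applied once to the",
      "epochs; removal is an idempotent projection, interpolation rows sum to 1.")
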