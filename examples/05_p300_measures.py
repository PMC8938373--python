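"""P300 measurement: window-mean amplitude and 50% fractional-area latency.

For each subject and load level, trial-averaged Pz waveforms are measured in
the canonical 300-700 ms window.  The fractional-area latency is the time at
which half of the (rectified) area under the ERP in the window has
accumulated - more robust on noisy averages than peak picking.
"""

from nbackerp.recovery import measure_cohort
from nbackerp.simulate import simulate_cohort

subjects, gt = simulate_cohort(8, seed=7)
meas = measure_cohort(subjects, gt, n_trials=40, seed=9)

print(meas[["subject", "group", "nback", "amplitude_uV", "latency_ms"]]
      .round(1).to_string(index=False))
g = meas.groupby(["group", "nback"])[["amplitude_uV", "latency_ms"]].mean().round(1)
print("\ncondition means:\n", g)
print("\n# amplitude falls from 1-back to 2-back (memory-load effect) in both",
      "groups;\n# the clinical group's latency is shorter, most clearly at 2-back -",
      "\n# exactly the structure the generator injects.")
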