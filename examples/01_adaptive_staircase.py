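"""Adaptive n-back staircase driven by a capacity-limited observer.

The block level rises after >=90% accuracy, falls after <=70%, and the
session ends after two consecutive blocks at an unchanged level.  The mean
level across administered blocks ("mean n-back") is the behavioral
working-memory capacity score.
"""

from nbackerp.observers import CapacityLimitedObserver
from nbackerp.task import corsi_score, run_staircase

for capacity in (1.5, 3.0, 4.5):
    session = run_staircase(CapacityLimitedObserver(capacity=capacity), seed=7)
    print(f"capacity {capacity:.1f}: levels {session.levels} "
          f"-> mean n-back {session.mean_nback:.2f} ({session.termination})")
print("# mean n-back tracks the observer's capacity: the staircase converges",
      "to the load the observer can just sustain.\n")

outcomes = [(2, True), (3, True), (4, True), (5, True), (6, False), (6, False)]
score = corsi_score(outcomes)
print(f"Corsi outcomes {outcomes}")
print(f"span = {score.span} ({score.flag})")
print("# the span is the mean of the two longest correctly repeated sequences,",
      "after stopping at the second failure.")
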