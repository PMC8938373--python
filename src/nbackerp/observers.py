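"""Behavioral observer models for the adaptive n-back task.

The capacity-limited observer hits targets with a probability that falls off
smoothly as the block's memory load exceeds its capacity, presses rarely on
non-targets, and produces RTs that slow with load.  Driving the adaptive
staircase with such an observer yields a mean n-back near its capacity, which
is how simulated cohorts acquire realistic behavioral working-memory scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import TrialSequence


@dataclass
class CapacityLimitedObserver:
    """Probabilistic observer with a soft working-memory capacity limit.

    Hit probability: ``ceiling / (1 + exp((level - capacity) / softness))``;
    at loads well below capacity the observer is near-perfect, at capacity it
    performs between the staircase thresholds, and above it performance
    collapses.  False alarms occur independently at ``fa_rate`` per
    non-target.  RTs are Gaussian around ``rt_base + rt_slope * level``.
    """

    capacity: float = 3.0
    softness: float = 0.35
    ceiling: float = 0.98
    fa_rate: float = 0.02
    rt_base_ms: float = 450.0
    rt_slope_ms: float = 60.0
    rt_sd_ms: float = 90.0

    def hit_probability(self, level: int) -> float:
        return self.ceiling / (1.0 + np.exp((level - self.capacity) / self.softness))

    def respond(self, sequence: TrialSequence, rng: np.random.Generator):
        n = len(sequence)
        tgt = sequence.is_target
        p_hit = self.hit_probability(sequence.level)
        pressed = np.where(tgt, rng.random(n) < p_hit, rng.random(n) < self.fa_rate)
        rts = rng.normal(self.rt_base_ms + self.rt_slope_ms * sequence.level,
                         self.rt_sd_ms, size=n)
        rts = np.clip(rts, 150.0, 1990.0)
        rts[~pressed] = np.nan
        return pressed, rts


@dataclass
class EEGTaskObserver:
    """Observer for the fixed-order EEG n-back task.

    Unlike the adaptive task, the EEG task is not meant to push performance to
    its limit: both groups perform well above chance at 1-back and moderately
    at 2-back.  Hit probability is anchored at the control-group block means
    (~87% 1-back, ~67% 2-back) and shifts mildly with the subject's
    working-memory capacity relative to the control mean.
    """

    capacity: float = 3.2
    base_hit_rate: tuple[float, float] = (0.873, 0.672)  # (1-back, 2-back)
    capacity_ref: float = 3.2
    capacity_slope: float = 0.03  # hit-rate change per unit capacity
    fa_rate: float = 0.03
    rt_base_ms: float = 535.0
    rt_slope_ms: float = 63.0
    rt_sd_ms: float = 120.0

    def hit_probability(self, level: int) -> float:
        base = self.base_hit_rate[min(level, 2) - 1]
        return float(np.clip(base + self.capacity_slope * (self.capacity - self.capacity_ref),
                             0.05, 0.99))

    def respond(self, sequence: TrialSequence, rng: np.random.Generator):
        n = len(sequence)
        tgt = sequence.is_target
        p_hit = self.hit_probability(sequence.level)
        pressed = np.where(tgt, rng.random(n) < p_hit, rng.random(n) < self.fa_rate)
        rts = rng.normal(self.rt_base_ms + self.rt_slope_ms * sequence.level,
                         self.rt_sd_ms, size=n)
        rts = np.clip(rts, 150.0, 1990.0)
        rts[~pressed] = np.nan
        return pressed, rts


@dataclass
class DeterministicObserver:
    """Fixed accuracy per level; useful for hand-checkable staircase traces.

    ``accuracy_by_level`` maps level -> proportion of targets hit (hits are
    taken in trial order, so a block's accuracy is the floor of
    accuracy * n_targets over n_targets).  Levels not listed fall back to
    ``default_accuracy``.  Never false-alarms.
    """

    accuracy_by_level: dict | None = None
    default_accuracy: float = 0.0
    rt_ms: float = 500.0

    def respond(self, sequence: TrialSequence, rng: np.random.Generator):
        acc = (self.accuracy_by_level or {}).get(sequence.level, self.default_accuracy)
        tgt_idx = np.flatnonzero(sequence.is_target)
        n_hit = int(np.floor(acc * tgt_idx.size + 1e-9))
        pressed = np.zeros(len(sequence), dtype=bool)
        pressed[tgt_idx[:n_hit]] = True
        rts = np.where(pressed, self.rt_ms, np.nan)
        return pressed, rts
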