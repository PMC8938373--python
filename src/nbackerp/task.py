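"""N-back task logic: sequence generation, adaptive staircase, block and Corsi scoring.

Two task variants are implemented.  The *behavioral* variant is adaptive: each
block has ``level`` lead-in screens plus 20 critical screens of which exactly 6
are targets, and block accuracy moves the memory load up (>= 90% correct), down
(<= 70%) or leaves it unchanged, terminating after two consecutive blocks played
at an unchanged level.  The *EEG* variant is fixed-order: 100-trial blocks with
exactly 25 targets, and stimuli that would be a target at the other load level
(a 2-back repeat in a 1-back block, or an immediate repeat in a 2-back block)
are never presented, so that the two load conditions stay uncontaminated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

#: Default letter alphabet (the eight consonants of the auditory variant).
LETTER_ALPHABET = ("c", "g", "h", "k", "p", "q", "t", "w")
#: Abstract 4-locus alphabet for the visuospatial variant.
LOCUS_ALPHABET = ("NE", "SE", "SW", "NW")

#: Stimulus-onset asynchrony components, ms.
FIXATION_MS = 2000.0
STIMULUS_MS = 500.0
JITTER_STEP_MS = 17.0
JITTER_MAX_MS = 100.0
RESPONSE_WINDOW_MS = 2000.0


def jitter_grid() -> np.ndarray:
    """Allowed onset jitters: multiples of 17 ms within +/-100 ms."""
    kmax = int(JITTER_MAX_MS // JITTER_STEP_MS)
    return np.arange(-kmax, kmax + 1) * JITTER_STEP_MS


@dataclass(frozen=True)
class StaircaseRules:
    """Adaptive-staircase parameters (proportions, not percentages)."""

    up_threshold: float = 0.90
    down_threshold: float = 0.70
    start_level: int = 1
    min_level: int = 1
    max_level: int = 9
    max_blocks: int = 20
    targets_per_block: int = 6
    critical_screens: int = 20

    def __post_init__(self):
        if not (0 < self.down_threshold < self.up_threshold <= 1):
            raise ValueError("need 0 < down_threshold < up_threshold <= 1")
        if not (self.min_level <= self.start_level <= self.max_level):
            raise ValueError("need min_level <= start_level <= max_level")


@dataclass(frozen=True)
class EEGSequenceConfig:
    n_trials: int = 100
    n_targets: int = 25
    max_consecutive_target_pairs: int = 6
    alphabet: tuple[str, ...] = LETTER_ALPHABET
    other_level: int | None = None  # defaults to the complementary load (1<->2)


@dataclass
class Trial:
    position: int
    stimulus: str
    is_target: bool
    onset_jitter_ms: float


@dataclass
class TrialSequence:
    """One block's ordered trials plus its load level and alphabet."""

    trials: list[Trial]
    level: int
    mode: str
    alphabet: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def stimuli(self) -> list[str]:
        return [t.stimulus for t in self.trials]

    @property
    def is_target(self) -> np.ndarray:
        return np.array([t.is_target for t in self.trials], dtype=bool)

    @property
    def n_targets(self) -> int:
        return int(self.is_target.sum())

    def onsets_ms(self, start_ms: float = 0.0) -> np.ndarray:
        """Stimulus-onset times: one fixation+stimulus cycle per trial, jittered."""
        soa = FIXATION_MS + STIMULUS_MS
        base = start_ms + FIXATION_MS + soa * np.arange(len(self.trials))
        return base + np.array([t.onset_jitter_ms for t in self.trials])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position": [t.position for t in self.trials],
                "stimulus": self.stimuli,
                "is_target": self.is_target,
                "onset_jitter_ms": [t.onset_jitter_ms for t in self.trials],
                "level": self.level,
            }
        )


class SequenceConstraintError(RuntimeError):
    """Raised when no sequence can satisfy the placement constraints."""


def _place_targets(
    rng: np.random.Generator,
    n_slots: int,
    n_targets: int,
    first_allowed: int,
    max_consecutive_pairs: int,
    max_tries: int = 2000,
) -> np.ndarray:
    """Choose target positions with a cap on adjacent (consecutive) target pairs."""
    eligible = np.arange(first_allowed, n_slots)
    if n_targets > eligible.size:
        raise SequenceConstraintError(
            f"cannot place {n_targets} targets in {eligible.size} eligible slots"
        )
    if max_consecutive_pairs == 0:
        # direct uniform construction over non-adjacent sets (stars and bars):
        # rejection would almost never succeed at these densities
        m = eligible.size - (n_targets - 1)
        if m < n_targets:
            raise SequenceConstraintError("too many targets for a non-adjacent placement")
        base = np.sort(rng.choice(m, size=n_targets, replace=False))
        return first_allowed + base + np.arange(n_targets)
    for _ in range(max_tries):
        pos = np.sort(rng.choice(eligible, size=n_targets, replace=False))
        if np.sum(np.diff(pos) == 1) <= max_consecutive_pairs:
            return pos
    raise SequenceConstraintError("target placement constraints unsatisfiable")


def generate_sequence(
    level: int,
    mode: str,
    config: StaircaseRules | EEGSequenceConfig | None = None,
    seed: int | np.random.Generator = 0,
    alphabet: Sequence[str] | None = None,
) -> TrialSequence:
    """Generate one n-back block.

    Behavioral mode: ``level`` lead-in screens + ``critical_screens`` screens,
    exactly ``targets_per_block`` targets among the critical screens (lead-in
    screens can never be targets).  EEG mode: ``n_trials`` trials with exactly
    ``n_targets`` targets and the cross-level exclusion constraint.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if mode == "behavioral":
        rules = config if isinstance(config, StaircaseRules) else StaircaseRules()
        alpha = tuple(alphabet) if alphabet is not None else LOCUS_ALPHABET
        n = level + rules.critical_screens
        # behavioral variant: consecutive targets allowed (no cap)
        pos = _place_targets(rng, n, rules.targets_per_block, level, rules.critical_screens)
        forbidden = None
    elif mode == "eeg":
        cfg = config if isinstance(config, EEGSequenceConfig) else EEGSequenceConfig()
        alpha = tuple(alphabet) if alphabet is not None else cfg.alphabet
        if level not in (1, 2) and cfg.other_level is None:
            raise ValueError("eeg mode defines cross-level exclusion for levels 1 and 2 only")
        other = cfg.other_level if cfg.other_level is not None else (2 if level == 1 else 1)
        n = cfg.n_trials
        # In 1-back blocks a consecutive target would force s[i]==s[i-2] (a
        # 2-back match), violating the cross-level exclusion, so the effective
        # cap there is 0.
        cap = 0 if other > level else cfg.max_consecutive_target_pairs
        pos = _place_targets(rng, n, cfg.n_targets, max(level, other), cap)
        forbidden = other
    else:
        raise ValueError(f"unknown mode {mode!r}")

    is_target = np.zeros(n, dtype=bool)
    is_target[pos] = True
    if len(alpha) < 3:
        raise SequenceConstraintError("alphabet too small for the exclusion constraints")

    stimuli: list[str] = []
    for i in range(n):
        banned: set[str] = set()
        if forbidden is not None and i >= forbidden:
            banned.add(stimuli[i - forbidden])
        if is_target[i]:
            s = stimuli[i - level]
            if s in banned:  # cannot happen given the placement rules; guard anyway
                raise SequenceConstraintError(f"target at {i} conflicts with exclusion")
        else:
            if i >= level:
                banned.add(stimuli[i - level])
            choices = [a for a in alpha if a not in banned]
            s = choices[rng.integers(len(choices))]
        stimuli.append(s)

    grid = jitter_grid()
    jit = grid[rng.integers(len(grid), size=n)]
    trials = [Trial(i, stimuli[i], bool(is_target[i]), float(jit[i])) for i in range(n)]
    return TrialSequence(trials=trials, level=level, mode=mode, alphabet=alpha)


# --------------------------------------------------------------------------- #
# scoring

MISSING_RT = float("nan")


@dataclass
class BlockScore:
    """Per-block performance summary.

    ``accuracy`` (hits/targets) drives the staircase; ``hits_minus_fa_pct``
    (percentage-point hit rate minus false-alarm rate) is the EEG-task
    performance metric; ``mean_rt_ms`` averages RTs of correct target presses
    and is NaN when no target was hit.
    """

    level: int
    n_targets: int
    n_nontargets: int
    hits: int
    false_alarms: int
    accuracy: float
    hits_minus_fa_pct: float
    mean_rt_ms: float

    @property
    def rt_missing(self) -> bool:
        return np.isnan(self.mean_rt_ms)


def score_block(
    sequence: TrialSequence,
    responses: Sequence[bool],
    rts_ms: Sequence[float] | None = None,
    response_window_ms: float = RESPONSE_WINDOW_MS,
) -> BlockScore:
    """Score one block from per-trial responses (press / no press).

    ``rts_ms`` gives per-trial response times; presses slower than the response
    window do not count.  Only responses on target trials are hits; any press
    on a non-target is a false alarm.
    """
    if len(responses) != len(sequence):
        raise ValueError(f"{len(responses)} responses for {len(sequence)} trials")
    pressed = np.asarray(responses, dtype=bool)
    if rts_ms is not None:
        if len(rts_ms) != len(sequence):
            raise ValueError("rts length mismatch")
        rts = np.asarray(rts_ms, dtype=float)
        pressed = pressed & ~(rts > response_window_ms)
    else:
        rts = np.full(len(sequence), np.nan)

    tgt = sequence.is_target
    hits = int(np.sum(pressed & tgt))
    fas = int(np.sum(pressed & ~tgt))
    n_t = int(tgt.sum())
    n_nt = int((~tgt).sum())
    accuracy = hits / n_t if n_t else 0.0
    hit_rate = 100.0 * hits / n_t if n_t else 0.0
    fa_rate = 100.0 * fas / n_nt if n_nt else 0.0
    hit_rts = rts[pressed & tgt]
    hit_rts = hit_rts[np.isfinite(hit_rts)]
    mean_rt = float(np.mean(hit_rts)) if hit_rts.size else MISSING_RT
    return BlockScore(
        level=sequence.level,
        n_targets=n_t,
        n_nontargets=n_nt,
        hits=hits,
        false_alarms=fas,
        accuracy=accuracy,
        hits_minus_fa_pct=hit_rate - fa_rate,
        mean_rt_ms=mean_rt,
    )


# --------------------------------------------------------------------------- #
# adaptive staircase


class Observer(Protocol):
    """Behavioral model: produces per-trial presses and RTs for a block."""

    def respond(
        self, sequence: TrialSequence, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (pressed, rt_ms) arrays aligned to the sequence's trials."""
        ...


@dataclass
class BlockRecord:
    level: int
    score: BlockScore


@dataclass
class StaircaseSession:
    """Full adaptive session: block trace, termination reason, summary scores."""

    blocks: list[BlockRecord]
    termination: str  # "unchanged_twice" or "max_blocks"

    @property
    def levels(self) -> list[int]:
        return [b.level for b in self.blocks]

    @property
    def mean_nback(self) -> float:
        return float(np.mean(self.levels))

    @property
    def mean_rt_ms(self) -> float:
        rts = [b.score.mean_rt_ms for b in self.blocks if not np.isnan(b.score.mean_rt_ms)]
        return float(np.mean(rts)) if rts else MISSING_RT


def next_level(level: int, accuracy: float, rules: StaircaseRules) -> int:
    """Apply the 90/70 up/down rule with floor and cap."""
    if accuracy >= rules.up_threshold:
        level += 1
    elif accuracy <= rules.down_threshold:
        level -= 1
    return int(np.clip(level, rules.min_level, rules.max_level))


def run_staircase(
    observer: Observer,
    rules: StaircaseRules | None = None,
    seed: int | np.random.Generator = 0,
    alphabet: Sequence[str] | None = None,
) -> StaircaseSession:
    """Run the adaptive n-back session to termination.

    Terminates after the second consecutive block played at an unchanged level
    (the counter resets whenever the level moves), or at ``max_blocks``.
    """
    rules = rules or StaircaseRules()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    level = rules.start_level
    prev_level: int | None = None
    blocks: list[BlockRecord] = []
    unchanged_streak = 0
    termination = "max_blocks"
    while len(blocks) < rules.max_blocks:
        seq = generate_sequence(level, "behavioral", rules, rng, alphabet=alphabet)
        pressed, rts = observer.respond(seq, rng)
        score = score_block(seq, pressed, rts)
        blocks.append(BlockRecord(level=level, score=score))
        # a block counts as "unchanged" when played at its predecessor's level;
        # the streak resets whenever the level moves
        if prev_level is not None:
            unchanged_streak = unchanged_streak + 1 if level == prev_level else 0
        if unchanged_streak >= 2:
            termination = "unchanged_twice"
            break
        prev_level = level
        level = next_level(level, score.accuracy, rules)
    return StaircaseSession(blocks=blocks, termination=termination)


# --------------------------------------------------------------------------- #
# Corsi blocks


@dataclass
class CorsiScore:
    span: float
    flag: str  # "ok", "single-span", "no-span"
    n_correct: int


def corsi_score(trial_outcomes: Sequence[tuple[int, bool]]) -> CorsiScore:
    """Score a Corsi blocks run: mean of the two longest correct sequences.

    ``trial_outcomes`` is the ordered list of (sequence length, correct) pairs.
    The run terminates at the second incorrect repetition; outcomes beyond that
    point are ignored.  With fewer than two correct sequences the single length
    (or 0) is returned with a flag.
    """
    correct_lengths: list[int] = []
    failures = 0
    for length, ok in trial_outcomes:
        if ok:
            correct_lengths.append(int(length))
        else:
            failures += 1
            if failures >= 2:
                break
    if not correct_lengths:
        return CorsiScore(span=0.0, flag="no-span", n_correct=0)
    if len(correct_lengths) == 1:
        return CorsiScore(span=float(correct_lengths[0]), flag="single-span", n_correct=1)
    top2 = sorted(correct_lengths)[-2:]
    return CorsiScore(span=float(np.mean(top2)), flag="ok", n_correct=len(correct_lengths))
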