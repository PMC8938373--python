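"""P300 measurement: trial selection and balancing, averaging, amplitude and
fractional-area latency.

The canonical measurement is the 300-700 ms window on channel Pz: time-window
averaged amplitude and the 50% fractional-area latency (the time point at
which half of the waveform's area within the window has accumulated).  The
window splits into an early (300-500 ms) and a late (500-700 ms) half for
topographic analysis over four 7-channel regions of interest.

Area for the latency measure uses the positive part of the waveform by default
(negative samples clipped to zero): the P300 is a positivity, and with signed
area the 50% crossing is not guaranteed to be monotone in time.  A signed-area
mode is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import Montage
from .preprocess import EpochSet


def _measure_mask(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    """Measurement windows include both endpoint samples (300-700 ms keeps the
    700 ms sample), unlike the half-open epoching windows."""
    t = np.asarray(times_ms)
    eps = 1e-9
    return (t >= window_ms[0] - eps) & (t <= window_ms[1] + eps)

logger = logging.getLogger(__name__)

REJECTION_THRESHOLD_UV = 120.0
FULL_WINDOW_MS = (300.0, 700.0)
EARLY_WINDOW_MS = (300.0, 500.0)
LATE_WINDOW_MS = (500.0, 700.0)
LOW_TRIAL_COUNT = 10


@dataclass
class Evoked:
    """Condition-averaged waveform (channels x samples, microvolts)."""

    condition: str
    ch_names: list[str]
    data: np.ndarray
    times_ms: np.ndarray
    n_trials: int

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.n_trials < 1:
            raise ValueError("an Evoked needs at least one trial")

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]


# --------------------------------------------------------------------------- #
# trial selection


def select_valid_trials(
    epochs: EpochSet,
    amplitude_threshold_uv: float = REJECTION_THRESHOLD_UV,
    eeg_channels: list[str] | None = None,
    require_correct: bool = True,
) -> EpochSet:
    """Flag trials exceeding the amplitude threshold on any EEG channel, and
    incorrect trials, as invalid.

    A trial is rejected when any |value| is strictly greater than the
    threshold, or when its ``correct`` metadata is false.  Flags are combined
    with (AND-ed into) any existing validity flags.
    """
    out = epochs.copy()
    if eeg_channels is None:
        rows = slice(None)
    else:
        rows = out.channel_index(eeg_channels)
    peak = np.abs(out.data[:, rows, :]).max(axis=(1, 2))
    ok = peak <= amplitude_threshold_uv
    if require_correct and "correct" in out.metadata.columns:
        ok &= out.metadata["correct"].to_numpy().astype(bool)
    out.valid = out.valid & ok
    logger.info(
        "trial selection: %d/%d retained (threshold %.0f uV)",
        int(out.valid.sum()),
        out.n_trials,
        amplitude_threshold_uv,
    )
    return out


def balance_nontargets(epochs: EpochSet, block_col: str = "block") -> EpochSet:
    """Keep, per block, one temporally proximal valid non-target per valid target.

    For each valid target trial in temporal order, the not-yet-selected valid
    non-target with the smallest |trial-index difference| is selected; ties go
    to the earlier trial.  All other non-targets are flagged invalid.
    """
    out = epochs.copy()
    tgt = out.metadata["is_target"].to_numpy().astype(bool)
    idx = np.arange(out.n_trials)
    blocks = out.metadata[block_col].to_numpy() if block_col in out.metadata else np.zeros(out.n_trials)
    selected = np.zeros(out.n_trials, dtype=bool)
    for b in pd.unique(blocks):
        inb = blocks == b
        targets = idx[inb & tgt & out.valid]
        pool = list(idx[inb & ~tgt & out.valid])
        if targets.size == 0:
            logger.warning("block %r: no valid targets; all non-targets dropped", b)
            continue
        order = out.metadata.get("position", pd.Series(idx)).to_numpy()
        for t in sorted(targets, key=lambda i: order[i]):
            if not pool:
                break
            dist = [abs(order[c] - order[t]) for c in pool]
            j = int(np.lexsort((np.array([order[c] for c in pool]), np.array(dist)))[0])
            selected[pool.pop(j)] = True
    out.valid = out.valid & (tgt | selected)
    return out


# --------------------------------------------------------------------------- #
# averaging


def average_evoked(epochs: EpochSet, condition: str = "", mask=None) -> Evoked:
    """Average the valid trials (optionally restricted by a boolean mask)."""
    use = epochs.valid if mask is None else (epochs.valid & np.asarray(mask, dtype=bool))
    n = int(use.sum())
    if n == 0:
        raise ValueError(f"no valid trials for condition {condition!r}")
    return Evoked(condition, list(epochs.ch_names), epochs.data[use].mean(axis=0),
                  epochs.times_ms, n)


def grand_average(evokeds: list[Evoked]) -> Evoked:
    """Unweighted mean over subjects' evoked responses."""
    if not evokeds:
        raise ValueError("empty evoked list")
    ref = evokeds[0]
    for e in evokeds[1:]:
        if e.ch_names != ref.ch_names or not np.allclose(e.times_ms, ref.times_ms):
            raise ValueError("evoked axes do not match")
    data = np.mean([e.data for e in evokeds], axis=0)
    return Evoked(ref.condition, list(ref.ch_names), data, ref.times_ms, len(evokeds))


def difference_wave(a: Evoked, b: Evoked, condition: str | None = None) -> Evoked:
    """Sample-wise a - b (e.g. target minus non-target)."""
    if a.ch_names != b.ch_names or not np.allclose(a.times_ms, b.times_ms):
        raise ValueError("evoked axes do not match")
    name = condition if condition is not None else f"{a.condition}-{b.condition}"
    return Evoked(name, list(a.ch_names), a.data - b.data, a.times_ms,
                  min(a.n_trials, b.n_trials))


# --------------------------------------------------------------------------- #
# measures


def _site_rows(evoked: Evoked, site: str, montage: Montage | None) -> list[int]:
    if site in evoked.ch_names:
        return [evoked.ch_names.index(site)]
    if montage is not None and site in montage.roi_map:
        return [evoked.ch_names.index(c) for c in montage.roi_map[site]]
    raise KeyError(f"unknown site {site!r}")


def window_amplitude(
    evoked: Evoked,
    site: str,
    window_ms: tuple[float, float] = FULL_WINDOW_MS,
    montage: Montage | None = None,
) -> float:
    """Mean amplitude (microvolts) over the window, at a channel or 7-channel ROI."""
    rows = _site_rows(evoked, site, montage)
    mask = _measure_mask(evoked.times_ms, window_ms)
    if not mask.any():
        raise ValueError("window contains no samples")
    return float(evoked.data[np.ix_(rows, mask)].mean())


class UndefinedLatency(ValueError):
    """Raised when the (rectified) area in the window is zero."""


def fractional_area_latency(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float] = FULL_WINDOW_MS,
    fraction: float = 0.5,
    rectify: bool = True,
) -> float:
    """Latency (ms) at which ``fraction`` of the waveform's area is reached.

    The waveform (one channel) is restricted to the window; negative values
    are clipped to zero unless ``rectify=False``.  Cumulative area is computed
    by trapezoidal integration on the sample grid and the crossing located by
    linear interpolation between samples.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    w = np.asarray(waveform, dtype=float)
    t = np.asarray(times_ms, dtype=float)
    mask = _measure_mask(t, window_ms)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    w, t = w[mask], t[mask]
    if rectify:
        w = np.clip(w, 0.0, None)
    # cumulative trapezoid: area up to each sample
    seg = 0.5 * (w[1:] + w[:-1]) * np.diff(t)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise UndefinedLatency("zero total area in window; latency undefined")
    target = fraction * total
    k = int(np.searchsorted(cum, target))
    k = min(max(k, 1), len(cum) - 1)
    # invert the quadratic cumulative of the linear segment [k-1, k]
    a0, a1 = cum[k - 1], cum[k]
    t0, t1 = t[k - 1], t[k]
    w0, w1 = w[k - 1], w[k]
    need = target - a0
    dt = t1 - t0
    if a1 == a0:
        return float(t0)
    slope = (w1 - w0) / dt
    if abs(slope) < 1e-15 * max(abs(w0), 1.0):
        x = need / w0 if w0 > 0 else 0.0
    else:
        disc = w0 * w0 + 2.0 * slope * need
        x = (-w0 + np.sqrt(max(disc, 0.0))) / slope
    return float(t0 + np.clip(x, 0.0, dt))


# --------------------------------------------------------------------------- #
# tidy measures table


def measure_p300(
    evoked_by_condition: dict[str, Evoked],
    montage: Montage,
    subject: str = "",
    group: str = "",
    pz: str = "Pz",
) -> pd.DataFrame:
    """Compute the standard measures table for one subject.

    For each condition Evoked: window-mean amplitude at Pz and at each ROI for
    the full/early/late windows, plus the 50% fractional-area latency at Pz in
    the full window.  Returns a tidy frame (one row per condition x window x
    site); undefined latencies are recorded as NaN and logged.
    """
    rows = []
    windows = {"full": FULL_WINDOW_MS, "early": EARLY_WINDOW_MS, "late": LATE_WINDOW_MS}
    for cond, ev in evoked_by_condition.items():
        for wname, win in windows.items():
            sites = [pz] + list(montage.roi_map)
            for site in sites:
                amp = window_amplitude(ev, site, win, montage)
                lat = np.nan
                if site == pz and wname == "full":
                    try:
                        lat = fractional_area_latency(ev.channel(pz), ev.times_ms, win)
                    except UndefinedLatency:
                        logger.warning("subject %s cond %s: undefined latency", subject, cond)
                rows.append(
                    dict(subject=subject, group=group, condition=cond, window=wname,
                         site=site, amplitude_uV=amp, latency_ms=lat, n_trials=ev.n_trials,
                         low_trial=ev.n_trials < LOW_TRIAL_COUNT)
                )
    return pd.DataFrame(rows)
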