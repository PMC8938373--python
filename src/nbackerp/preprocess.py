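"""Deterministic signal conditioning: re-referencing, filtering, resampling, epoching.

The conditioning chain mirrors a conventional ERP pipeline: continuous data are
re-referenced to the averaged mastoids, down-sampled to 200 Hz, high-pass
(0.1 Hz), low-pass (120 Hz) and notch (48-52 Hz) filtered, then cut into
epochs (-600 to 1400 ms around stimulus onset).  For ERP measurement the
epochs are cropped to -100..900 ms, baseline-corrected on -100..0 ms and
low-pass filtered at 30 Hz.

All filters are zero-phase (forward-backward) Butterworth of order 4;
resampling is polyphase with anti-aliasing.  Time windows are half-open on the
sample grid, [start, end), with t = 0 at the stimulus-onset sample.  Units are
microvolts throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .montage import AUX_CHANNELS

logger = logging.getLogger(__name__)

FILTER_ORDER = 4


@dataclass
class ContinuousRecording:
    """Multichannel continuous time series with stimulus events.

    ``data`` is channels x samples in microvolts; ``events`` carries one row
    per stimulus with a ``sample`` column (0-based index into the recording)
    plus arbitrary trial metadata columns (block, level, target flag, ...).
    """

    sfreq: float
    ch_names: list[str]
    data: np.ndarray
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame({"sample": []}))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ValueError("data must be (n_channels, n_samples) matching ch_names")
        if self.sfreq <= 0:
            raise ValueError("sample rate must be positive")
        if len(self.events) and not self.events["sample"].is_monotonic_increasing:
            raise ValueError("event samples must be increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, names) -> np.ndarray:
        return np.array([self.ch_names.index(n) for n in names])

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            self.sfreq, list(self.ch_names), self.data.copy(), self.events.copy()
        )


@dataclass
class EpochSet:
    """Trials x channels x samples with per-trial metadata and validity flags."""

    sfreq: float
    ch_names: list[str]
    tmin_ms: float
    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    metadata: pd.DataFrame
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.data.shape[0], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials, channels, samples)")
        if len(self.metadata) != self.data.shape[0] or self.valid.size != self.data.shape[0]:
            raise ValueError("metadata/flags length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis: tmin + k/sfreq, with 0 at the stimulus-onset sample."""
        n = self.data.shape[2]
        return self.tmin_ms + 1000.0 * np.arange(n) / self.sfreq

    def channel_index(self, names) -> np.ndarray:
        return np.array([self.ch_names.index(n) for n in names])

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.sfreq,
            list(self.ch_names),
            self.tmin_ms,
            self.data.copy(),
            self.metadata.copy().reset_index(drop=True),
            self.valid.copy(),
        )


# --------------------------------------------------------------------------- #


def rereference(
    recording: ContinuousRecording,
    reference_channels=("M1", "M2"),
    exclude=AUX_CHANNELS,
) -> ContinuousRecording:
    """Subtract the mean of the reference channels from every scalp channel.

    Channels in ``exclude`` (EOG and the references themselves) are passed
    through unchanged; the reference channels are retained in the output.
    """
    missing = [c for c in reference_channels if c not in recording.ch_names]
    if missing:
        raise ValueError(f"reference channels missing from recording: {missing}")
    out = recording.copy()
    ref = out.data[out.channel_index(reference_channels)].mean(axis=0)
    skip = set(exclude) | set(reference_channels)
    rows = [i for i, c in enumerate(out.ch_names) if c not in skip]
    out.data[rows] -= ref
    return out


def _sos_filter(data: np.ndarray, sfreq: float, btype: str, cutoff) -> np.ndarray:
    nyq = sfreq / 2.0
    wn = np.atleast_1d(np.asarray(cutoff, dtype=float)) / nyq
    if np.any(wn <= 0) or np.any(wn >= 1):
        raise ValueError(f"cutoff {cutoff} outside (0, Nyquist={nyq}) Hz")
    sos = signal.butter(FILTER_ORDER, wn if wn.size > 1 else wn[0], btype=btype, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def filter_resample(
    recording: ContinuousRecording,
    highpass: float | None = 0.1,
    lowpass: float | None = 120.0,
    notch_band: tuple[float, float] | None = (48.0, 52.0),
    target_rate: float | None = 200.0,
    resample_first: bool = True,
) -> ContinuousRecording:
    """Zero-phase filtering and anti-aliased resampling.

    Default stage order is resample -> high-pass -> low-pass -> notch (the
    resampler applies its own anti-aliasing low-pass); set
    ``resample_first=False`` to filter at the original rate instead.  Event
    sample indices are rescaled to the new rate.
    """
    out = recording.copy()

    def _apply_filters(rec: ContinuousRecording) -> None:
        nyq = rec.sfreq / 2.0
        for btype, cut in (("highpass", highpass), ("lowpass", lowpass), ("bandstop", notch_band)):
            if cut is None:
                continue
            if btype != "highpass" and np.max(np.atleast_1d(cut)) >= nyq:
                # e.g. a 120 Hz low-pass after down-sampling to 200 Hz: the
                # resampler's anti-aliasing already band-limits the data
                logger.info("skipping %s filter at %s Hz (Nyquist %.1f Hz)", btype, cut, nyq)
                continue
            rec.data = _sos_filter(rec.data, rec.sfreq, btype, cut)

    def _resample(rec: ContinuousRecording) -> ContinuousRecording:
        if target_rate is None or target_rate == rec.sfreq:
            return rec
        from fractions import Fraction

        frac = Fraction(target_rate / rec.sfreq).limit_denominator(1000)
        data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
        events = rec.events.copy()
        if len(events):
            events["sample"] = np.round(
                events["sample"].to_numpy() * target_rate / rec.sfreq
            ).astype(int)
        return ContinuousRecording(float(target_rate), list(rec.ch_names), data, events)

    if resample_first:
        out = _resample(out)
        _apply_filters(out)
    else:
        _apply_filters(out)
        out = _resample(out)
    return out


def epoch_baseline(
    recording: ContinuousRecording,
    window_ms: tuple[float, float] = (-600.0, 1400.0),
    baseline_ms: tuple[float, float] | None = (-100.0, 0.0),
    crop_ms: tuple[float, float] | None = None,
    lowpass_post: float | None = None,
) -> EpochSet:
    """Cut epochs around each event, baseline-correct, optionally crop + low-pass.

    Epochs are cut on the sample grid: the window [start, end) in ms maps to
    sample offsets [round(start*fs), round(end*fs)).  The per-epoch, per-channel
    mean over the baseline interval is subtracted.  Events whose window exceeds
    the recording edges are dropped and logged.
    """
    fs = recording.sfreq
    lo = int(round(window_ms[0] * fs / 1000.0))
    hi = int(round(window_ms[1] * fs / 1000.0))
    if not (lo <= 0 < hi):
        raise ValueError("epoch window must contain time 0")
    rows, kept = [], []
    for i, ev in recording.events.iterrows():
        s = int(ev["sample"])
        if s + lo < 0 or s + hi > recording.n_samples:
            logger.warning("dropping event %d at sample %d: epoch exceeds recording", i, s)
            continue
        rows.append(recording.data[:, s + lo : s + hi])
        kept.append(i)
    if not rows:
        raise ValueError("no events with a full epoch window inside the recording")
    data = np.stack(rows)
    meta = recording.events.loc[kept].reset_index(drop=True)
    epochs = EpochSet(fs, list(recording.ch_names), 1000.0 * lo / fs, data, meta)
    if baseline_ms is not None:
        epochs = baseline_correct(epochs, baseline_ms)
    if crop_ms is not None:
        epochs = crop(epochs, crop_ms)
    if lowpass_post is not None:
        epochs.data = _sos_filter(epochs.data, fs, "lowpass", lowpass_post)
    return epochs


def window_slice(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    """Boolean mask for the half-open window [start, end) on the time axis."""
    t = np.asarray(times_ms)
    # guard the open edge against float round-off on the sample grid
    eps = 1e-9
    return (t >= window_ms[0] - eps) & (t < window_ms[1] - eps)


def baseline_correct(epochs: EpochSet, baseline_ms=(-100.0, 0.0)) -> EpochSet:
    out = epochs.copy()
    mask = window_slice(out.times_ms, baseline_ms)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def crop(epochs: EpochSet, crop_ms: tuple[float, float]) -> EpochSet:
    mask = window_slice(epochs.times_ms, crop_ms)
    if not mask.any():
        raise ValueError("crop window contains no samples")
    first = int(np.flatnonzero(mask)[0])
    out = epochs.copy()
    out.data = out.data[:, :, mask]
    out.tmin_ms = float(epochs.times_ms[first])
    return out
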