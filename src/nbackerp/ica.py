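"""Ocular-artifact identification and removal via z-scored ICA component scoring.

The procedure: 32 independent components are extracted from the 64 EEG
channels (EOG and mastoids excluded).  Each component's time-course is
correlated with the VEOG and HEOG channels, and its channel-weight map with
the participant's average blink topography (all signals band-passed 1-20 Hz
before temporal correlation).  Each correlation set is z-scored *across
components* - subtracting the mean of all 32 correlations and dividing by
their SD - so the score indexes how unusual a component's artifact
correlation is relative to the others, not its raw magnitude.  Components
with any |z| > 2 become suspects; a suspect is removed only if its raw
|correlation| also exceeds a floor (default 0.2), an automatic stand-in for
the visual confirmation step, with an operator override hook.

Removal is a channel-space projection matrix (identity minus the removed
components' mixing-unmixing outer product); noisy channels get a separate
interpolation matrix (inverse great-circle-distance weights over the 6
nearest good channels).  The two matrices compose into a single cleaning
montage applied once to the epoched data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

from .montage import AUX_CHANNELS, Montage
from .preprocess import ContinuousRecording, EpochSet, _sos_filter

logger = logging.getLogger(__name__)

SUSPECT_Z = 2.0
CONFIRM_MIN_ABS_CORR = 0.2
SCORING_BAND_HZ = (1.0, 20.0)
BLINK_BAND_HZ = (1.0, 15.0)
BLINK_THRESHOLD_MADS = 5.0
BLINK_REFRACTORY_MS = 300.0
BLINK_EPOCH_MS = (-100.0, 300.0)
BLINK_TOPO_WINDOW_MS = (50.0, 250.0)
BAD_CHANNEL_Z = 4.0


@dataclass
class ICAModel:
    """Fitted unmixing/mixing weights plus per-component artifact scores."""

    ch_names: list[str]
    n_components: int
    unmixing: np.ndarray  # components x channels
    mixing: np.ndarray  # channels x components
    mean: np.ndarray  # per-channel mean removed before unmixing
    sources: np.ndarray  # components x samples (fit data)
    seed: int
    corr: dict[str, np.ndarray] = field(default_factory=dict)
    zscores: dict[str, np.ndarray] = field(default_factory=dict)
    suspects: np.ndarray | None = None
    removed: list[int] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def get_sources(self, data: np.ndarray) -> np.ndarray:
        """Component time-courses for (channels x samples) data."""
        return self.unmixing @ (data - self.mean[:, None])


def _epochs_to_matrix(epochs: EpochSet, ch_names: list[str]) -> np.ndarray:
    idx = epochs.channel_index(ch_names)
    d = epochs.data[epochs.valid][:, idx, :]
    return d.transpose(1, 0, 2).reshape(len(ch_names), -1)


def fit_ica(
    data: EpochSet | ContinuousRecording | np.ndarray,
    n_components: int = 32,
    seed: int = 0,
    ch_names: list[str] | None = None,
) -> ICAModel:
    """Extract ``n_components`` independent components from the EEG channels.

    ``data`` may be an EpochSet (valid epochs concatenated), a continuous
    recording, or a raw (channels x samples) matrix.  EOG/mastoid channels are
    excluded automatically.  Dimensionality is reduced (PCA whitening) to
    ``n_components`` before unmixing; components are ordered by explained
    channel-space variance; the fit is deterministic under a fixed seed.
    """
    if isinstance(data, EpochSet) or isinstance(data, ContinuousRecording):
        names = ch_names or [c for c in data.ch_names if c not in AUX_CHANNELS]
        if isinstance(data, EpochSet):
            X = _epochs_to_matrix(data, names)
        else:
            X = data.data[data.channel_index(names)]
    else:
        X = np.asarray(data, dtype=float)
        names = ch_names or [f"ch{i}" for i in range(X.shape[0])]
    n_ch = X.shape[0]
    if n_components > n_ch:
        raise ValueError(f"requested {n_components} components from {n_ch} channels")
    rank = np.linalg.matrix_rank(np.cov(X))
    if rank < n_components:
        logger.warning("data rank %d < %d requested components; reducing", rank, n_components)
        n_components = int(rank)

    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        random_state=int(seed),
        max_iter=1000,
        tol=1e-6,
    )
    sources = ica.fit_transform(X.T).T  # components x samples
    unmixing = ica.components_
    mixing = np.linalg.pinv(unmixing)
    # order by explained channel-space variance (sources are unit variance)
    power = np.sum(mixing**2, axis=0) * np.var(sources, axis=1)
    order = np.argsort(power)[::-1]
    return ICAModel(
        ch_names=list(names),
        n_components=n_components,
        unmixing=unmixing[order],
        mixing=mixing[:, order],
        mean=ica.mean_.copy(),
        sources=sources[order],
        seed=int(seed),
    )


# --------------------------------------------------------------------------- #
# blink detection


@dataclass
class BlinkResult:
    events: np.ndarray  # sample indices of blink peaks
    topography: np.ndarray | None  # per-EEG-channel blink map, or None
    ch_names: list[str] | None = None

    @property
    def available(self) -> bool:
        return self.topography is not None


def detect_blinks(
    veog: np.ndarray,
    sfreq: float,
    threshold_mads: float = BLINK_THRESHOLD_MADS,
    refractory_ms: float = BLINK_REFRACTORY_MS,
    band_hz: tuple[float, float] = BLINK_BAND_HZ,
    suppression_ms: float = 1200.0,
    suppression_ratio: float = 3.0,
) -> np.ndarray:
    """Blink peak samples: conditioned VEOG above median + k*MAD, with refractory gap.

    Conditioning uses a gentle (order-2, zero-phase) band-pass: a steeper
    high-pass leaves each blink flanked by rebound shoulders large enough to
    clear the threshold as spurious events.  Residual shoulders are removed
    by amplitude-aware suppression: a candidate peak is discarded when a
    much larger peak (height ratio above ``suppression_ratio``) was accepted
    within ``suppression_ms`` - genuine consecutive blinks have comparable
    heights and survive.
    """
    nyq = sfreq / 2.0
    sos = signal.butter(2, [band_hz[0] / nyq, band_hz[1] / nyq], "bandpass", output="sos")
    x = signal.sosfiltfilt(sos, np.asarray(veog, dtype=float))
    mad = np.median(np.abs(x - np.median(x)))
    if mad == 0:
        return np.array([], dtype=int)
    thresh = np.median(x) + threshold_mads * mad
    dist = max(int(round(refractory_ms * sfreq / 1000.0)), 1)
    peaks, props = signal.find_peaks(x, height=thresh, distance=dist)
    if peaks.size == 0:
        return peaks
    supp = suppression_ms * sfreq / 1000.0
    accepted: list[tuple[int, float]] = []
    for p, h in sorted(zip(peaks, props["peak_heights"]), key=lambda t: -t[1]):
        if all(abs(p - a) > supp or ha <= suppression_ratio * h for a, ha in accepted):
            accepted.append((int(p), float(h)))
    return np.array(sorted(p for p, _ in accepted), dtype=int)


def blink_topography(
    eeg_data: np.ndarray,
    blink_events: np.ndarray,
    sfreq: float,
    epoch_ms: tuple[float, float] = BLINK_EPOCH_MS,
    topo_window_ms: tuple[float, float] = BLINK_TOPO_WINDOW_MS,
) -> np.ndarray | None:
    """Average blink-locked EEG and take the 50-250 ms window mean per channel.

    Returns None (topography unavailable) when no blink epoch fits the data.
    """
    lo = int(round(epoch_ms[0] * sfreq / 1000.0))
    hi = int(round(epoch_ms[1] * sfreq / 1000.0))
    segs = [
        eeg_data[:, s + lo : s + hi]
        for s in np.asarray(blink_events, dtype=int)
        if s + lo >= 0 and s + hi <= eeg_data.shape[1]
    ]
    if not segs:
        return None
    avg = np.mean(segs, axis=0)
    t = epoch_ms[0] + 1000.0 * np.arange(avg.shape[1]) / sfreq
    win = (t >= topo_window_ms[0]) & (t <= topo_window_ms[1])
    return avg[:, win].mean(axis=1)


def detect_blinks_and_topography(recording: ContinuousRecording, veog: str = "VEOG",
                                 eeg_channels: list[str] | None = None) -> BlinkResult:
    """Convenience wrapper: detect blinks on VEOG, build the EEG blink map."""
    if veog not in recording.ch_names:
        raise ValueError(f"channel {veog!r} not in recording")
    names = eeg_channels or [c for c in recording.ch_names if c not in AUX_CHANNELS]
    events = detect_blinks(recording.data[recording.ch_names.index(veog)], recording.sfreq)
    topo = None
    if events.size:
        topo = blink_topography(recording.data[recording.channel_index(names)],
                                events, recording.sfreq)
    if topo is None:
        logger.warning("no blinks detected; spatial scoring will be skipped")
    return BlinkResult(events=events, topography=topo, ch_names=names)


# --------------------------------------------------------------------------- #
# component scoring


def _zscore_across(values: np.ndarray, label: str, notes: list[str]) -> np.ndarray:
    sd = values.std()
    if sd < 1e-12:
        notes.append(f"{label}: zero spread in correlations; all z set to 0")
        logger.warning("%s: all component correlations equal; z-scores set to 0", label)
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``a`` with vector ``b``."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean()
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a @ b) / denom
    return np.where(np.isfinite(r), r, 0.0)


def score_components(
    ica: ICAModel,
    veog: np.ndarray,
    heog: np.ndarray,
    blink_topo: np.ndarray | None,
    sfreq: float,
    band_hz: tuple[float, float] = SCORING_BAND_HZ,
    suspect_z: float = SUSPECT_Z,
) -> ICAModel:
    """Correlate components with VEOG/HEOG and the blink map; z-score; flag suspects.

    Temporal correlations use the fitted component time-courses and the EOG
    channels, all band-passed 1-20 Hz; the spatial correlation compares each
    component's channel weights with the blink topography.  Each correlation
    set is z-scored across the component dimension; a component with any
    |z| > 2 is a suspect.
    """
    if veog is None or heog is None:
        raise ValueError("VEOG and HEOG signals are required for scoring")
    src = _sos_filter(ica.sources, sfreq, "bandpass", band_hz)
    v = _sos_filter(np.asarray(veog, dtype=float), sfreq, "bandpass", band_hz)
    h = _sos_filter(np.asarray(heog, dtype=float), sfreq, "bandpass", band_hz)
    if src.shape[1] != v.size or v.size != h.size:
        raise ValueError("EOG signals must be time-aligned with the ICA fit data")
    ica.corr["veog"] = _corr_rows(src, v)
    ica.corr["heog"] = _corr_rows(src, h)
    for key in ("veog", "heog"):
        ica.zscores[key] = _zscore_across(ica.corr[key], key, ica.notes)
    if blink_topo is not None:
        ica.corr["blink"] = _corr_rows(ica.mixing.T, np.asarray(blink_topo, dtype=float))
        ica.zscores["blink"] = _zscore_across(ica.corr["blink"], "blink", ica.notes)
    else:
        ica.notes.append("blink topography unavailable; spatial scoring skipped")
    zmat = np.vstack([ica.zscores[k] for k in ica.zscores])
    ica.suspects = (np.abs(zmat) > suspect_z).any(axis=0)
    return ica


def select_removal(
    ica: ICAModel,
    min_abs_corr: float = CONFIRM_MIN_ABS_CORR,
    override: list[int] | None = None,
) -> list[int]:
    """Confirm suspects for removal: raw |correlation| must also exceed a floor.

    ``override`` replaces the automatic selection entirely (logged), mirroring
    the operator's prerogative in a visual-inspection workflow.
    """
    if override is not None:
        extra = set(override) - set(np.flatnonzero(ica.suspects if ica.suspects is not None else []))
        if extra:
            ica.notes.append(f"operator override removed non-suspect components {sorted(extra)}")
            logger.warning("override removes non-suspect components %s", sorted(extra))
        ica.removed = sorted(int(i) for i in override)
        return ica.removed
    if ica.suspects is None:
        raise ValueError("score_components must run before removal selection")
    cmat = np.vstack([ica.corr[k] for k in ica.corr])
    confirmed = np.abs(cmat).max(axis=0) > min_abs_corr
    ica.removed = sorted(int(i) for i in np.flatnonzero(ica.suspects & confirmed))
    return ica.removed


# --------------------------------------------------------------------------- #
# bad channels and the cleaning montage


def detect_bad_channels(
    epochs: EpochSet | np.ndarray,
    threshold_z: float = BAD_CHANNEL_Z,
    force: tuple[str, ...] = (),
    ch_names: list[str] | None = None,
) -> list[str]:
    """Channels whose robust variance z (median/MAD across channels) exceeds threshold.

    ``force`` lists channels always reported bad (e.g. a persistently noisy
    electrode known from the recording log).
    """
    if isinstance(epochs, EpochSet):
        names = ch_names or [c for c in epochs.ch_names if c not in AUX_CHANNELS]
        X = _epochs_to_matrix(epochs, names)
    else:
        X = np.asarray(epochs, dtype=float)
        names = ch_names or [f"ch{i}" for i in range(X.shape[0])]
    v = X.var(axis=1)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    bad: set[str] = set(c for c in force if c in names)
    if mad > 0:
        z = (v - med) / (1.4826 * mad)
        bad |= {names[i] for i in np.flatnonzero(z > threshold_z)}
    return sorted(bad, key=names.index)


@dataclass
class CleaningMontage:
    """Removal + interpolation matrices composed for one application to epochs."""

    ch_names: list[str]
    removal: np.ndarray
    interpolation: np.ndarray
    composed: np.ndarray
    bad_channels: list[str]
    provenance: dict = field(default_factory=dict)


def build_cleaning_montage(
    ica: ICAModel,
    removed_components: list[int],
    montage: Montage,
    bad_channels: list[str] | None = None,
    n_neighbors: int = 6,
) -> CleaningMontage:
    """Compose the component-removal projection with bad-channel interpolation.

    The removal matrix projects out the spatial subspace of the removed
    components (identity when none are removed).  Each bad channel's row in
    the interpolation matrix is an inverse great-circle-distance weighted
    average over its ``n_neighbors`` nearest good channels, normalized to sum
    to 1.  The composed matrix is interpolation @ removal.
    """
    names = ica.ch_names
    n = len(names)
    bad = list(bad_channels or [])
    unknown = [c for c in bad if c not in names]
    if unknown:
        raise ValueError(f"bad channels not in ICA channel set: {unknown}")
    if len(bad) >= n:
        raise ValueError("all channels bad; nothing to interpolate from")
    if any(k < 0 or k >= ica.n_components for k in removed_components):
        raise ValueError("removed component index out of range")

    removal = np.eye(n)
    if removed_components:
        r = list(removed_components)
        removal = removal - ica.mixing[:, r] @ ica.unmixing[r, :]

    interpolation = np.eye(n)
    good = [c for c in names if c not in bad]
    for c in bad:
        d = np.array([montage.geodesic_distances(c, [g])[0] for g in good])
        order = np.argsort(d)[:n_neighbors]
        w = 1.0 / np.maximum(d[order], 1e-6)
        w = w / w.sum()
        row = np.zeros(n)
        for g_i, w_i in zip(order, w):
            row[names.index(good[g_i])] = w_i
        interpolation[names.index(c)] = row

    return CleaningMontage(
        ch_names=list(names),
        removal=removal,
        interpolation=interpolation,
        composed=interpolation @ removal,
        bad_channels=bad,
        provenance=dict(
            removed_components=list(removed_components),
            n_suspects=int(ica.suspects.sum()) if ica.suspects is not None else None,
            ica_seed=ica.seed,
        ),
    )


def apply_cleaning(epochs: EpochSet, cleaning: CleaningMontage) -> EpochSet:
    """Apply the composed cleaning matrix once to the epoched EEG channels."""
    out = epochs.copy()
    idx = out.channel_index(cleaning.ch_names)
    out.data[:, idx, :] = np.einsum("ij,njt->nit", cleaning.composed, out.data[:, idx, :])
    return out
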