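"""Synthetic cohorts and EEG recordings with known ground truth.

The generator emulates the structure of a two-group (clinical vs control)
pediatric working-memory study: ~16 subjects per group aged 11-17, matched in
age and sex; standardized behavioral scores drawn from Gaussians with the
study's printed group means/SDs; and per-subject ERP ground truth - a
parietal-maximal P300 whose amplitude falls with memory load and whose
latency is shorter in the clinical group, most strongly at the higher load.

Continuous recordings are built at 512 Hz from: 1/f ("pink") background noise
per channel, a shared posterior alpha (10 Hz) source, a per-trial P300 pulse
(Gaussian in time, Gaussian spatial weighting in geodesic distance around Pz,
larger for targets and for the lower load), Poisson-rate blinks with a
frontal topography mirrored in VEOG, saccade steps in HEOG, and optional
high-variance bad channels.  Every random draw flows from one named seed via
documented sub-streams, so regeneration is bit-identical.

Ground-truth between-subject SDs are calibrated so that the *measured* P300
statistics (after trial averaging, which adds measurement noise) match the
study's printed standard errors; they are therefore somewhat smaller than the
printed cross-subject spreads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import Montage, make_montage
from .observers import CapacityLimitedObserver, EEGTaskObserver
from .preprocess import ContinuousRecording
from .task import EEGSequenceConfig, StaircaseRules, TrialSequence, generate_sequence, run_staircase

SFREQ = 512.0

#: Printed group means/SDs for the standardized measures (clinical, control).
DEFAULT_SCORES = {
    "conners_inattention": (73.63, 12.92, 48.81, 8.16),
    "conners_hyperactivity": (69.88, 18.53, 49.31, 8.90),
    "vineland_communication": (82.68, 18.07, 108.65, 8.05),
    "vineland_daily_living": (85.20, 16.58, 99.00, 16.97),
    "vineland_socialisation": (81.63, 20.72, 106.50, 9.34),
    "vineland_abc": (83.06, 16.58, 103.56, 15.35),
    "digit_span_forward": (6.75, 3.02, 10.56, 2.33),
    "digit_span_backward": (5.88, 1.31, 9.00, 2.31),
    "teach_sky_search": (10.5, 3.14, 10.81, 2.04),
    "teach_score": (9.13, 3.81, 11.44, 2.31),
    "teach_creature_counting": (8.62, 3.28, 11.31, 2.98),
    "teach_sky_search_dt": (7.88, 1.63, 8.19, 1.94),
    # behavioral WM capacity scores (not printed; see docs/methods.md)
    "mean_nback_visual": (1.9, 0.6, 3.1, 0.8),
    "mean_nback_auditory": (1.8, 0.6, 3.0, 0.8),
    "corsi_span": (4.5, 0.9, 5.3, 0.9),
}


@dataclass
class EffectConfig:
    """Ground-truth effect sizes for the simulated cohort.

    ERP defaults are the study's printed Results values: Pz target amplitude
    14.0 uV at 1-back vs 11.5 uV at 2-back, and a clinical-group latency
    shortening of ~20 ms at 1-back and ~55 ms at 2-back on a 1-back control
    baseline near 512 ms.  Between-subject SDs are split into a subject
    intercept and a condition-specific part, calibrated against the printed
    SEMs (see module docstring).
    """

    scores: dict = field(default_factory=lambda: dict(DEFAULT_SCORES))
    amp_1back_uv: float = 14.0
    amp_2back_uv: float = 11.5
    amp_intercept_sd: float = 5.1
    amp_condition_sd: float = 1.9
    nontarget_amp_frac: float = 0.35
    latency_1back_ms: float = 512.0
    load_latency_shift_ms: float = 21.7  # 2-back slower than 1-back (controls)
    group_latency_shift_1back_ms: float = -20.4
    group_latency_shift_2back_ms: float = -54.9
    latency_intercept_sd: float = 39.0
    latency_condition_sd: float = 23.0
    group_amp_shift_uv: float = 0.0  # no printed group amplitude difference
    capacity_mean: tuple[float, float] = (2.0, 3.2)  # (clinical, control)
    capacity_sd: tuple[float, float] = (0.6, 0.8)
    age_range: tuple[float, float] = (11.0, 17.0)
    male_fraction: float = 9.0 / 16.0


def default_effects() -> EffectConfig:
    return EffectConfig()


def null_effects() -> EffectConfig:
    """Groups identical on every score and every ERP parameter (for null tests)."""
    cfg = EffectConfig()
    pooled = {}
    for k, (m1, s1, m2, s2) in cfg.scores.items():
        m = 0.5 * (m1 + m2)
        s = np.sqrt(0.5 * (s1**2 + s2**2))
        pooled[k] = (m, s, m, s)
    return replace(
        cfg,
        scores=pooled,
        group_latency_shift_1back_ms=0.0,
        group_latency_shift_2back_ms=0.0,
        group_amp_shift_uv=0.0,
        capacity_mean=(2.6, 2.6),
        capacity_sd=(0.7, 0.7),
    )


@dataclass
class NoiseConfig:
    """Continuous-recording noise and artifact parameters (microvolts)."""

    background_rms_uv: float = 15.0  # total 1/f background per channel
    n_noise_sources: int = 20  # smooth spatial patterns carrying the background
    sensor_noise_frac: float = 0.45  # independent per-channel share of the RMS
    alpha_rms_uv: float = 4.0  # shared 10 Hz posterior source
    trial_amp_jitter: float = 0.12  # multiplicative SD on single-trial P300
    blink_rate_per_min: float = 12.0
    blink_amp_uv: float = 200.0
    blink_width_ms: float = 60.0  # Gaussian sigma
    blink_frontal_gain: float = 0.6
    saccade_rate_per_min: float = 4.0
    saccade_amp_uv: float = 35.0
    bad_channel_rms_uv: float = 120.0
    include_artifacts: bool = True


def noiseless() -> NoiseConfig:
    return NoiseConfig(
        background_rms_uv=0.0,
        alpha_rms_uv=0.0,
        trial_amp_jitter=0.0,
        blink_rate_per_min=0.0,
        saccade_rate_per_min=0.0,
        include_artifacts=False,
    )


P300_SIGMA_MS = 70.0
P300_SPATIAL_SIGMA_RAD = 0.5
BLINK_SPATIAL_SIGMA_RAD = 0.55

#: Window mean of a unit-peak Gaussian pulse (sigma 70 ms) centered in the
#: 300-700 ms analysis window.  Ground-truth amplitudes are *window-mean*
#: quantities (that is what the study reports), so the injected pulse peak is
#: amplitude / this gain.
PULSE_WINDOW_GAIN = float(
    np.mean(np.exp(-0.5 * ((np.arange(300.0, 700.5, 0.5) - 500.0) / P300_SIGMA_MS) ** 2))
)


# --------------------------------------------------------------------------- #
# cohort


def simulate_cohort(
    n_per_group: int = 16,
    effects: EffectConfig | None = None,
    seed: int = 0,
    groups: tuple[str, str] = ("nf1", "control"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the subject table and the per-subject ERP ground truth.

    Returns ``(subjects, ground_truth)``: one row per subject each.  The two
    groups are matched in age and sex (paired draws); behavioral scores come
    from per-group Gaussians; ERP ground truth holds each subject's true P300
    amplitude and latency per load level plus artifact parameters.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    eff = effects or default_effects()
    for key, val in eff.scores.items():
        if len(val) != 4:
            raise ValueError(f"malformed effect_config entry for {key!r}")
    root = np.random.SeedSequence(int(seed))
    # documented sub-streams: demographics, scores, erp, artifacts
    r_demo, r_scores, r_erp, r_art = [np.random.default_rng(s) for s in root.spawn(4)]

    lo, hi = eff.age_range
    base_age = r_demo.uniform(lo, hi, size=n_per_group)
    n_male = int(round(eff.male_fraction * n_per_group))
    sex = np.array(["M"] * n_male + ["F"] * (n_per_group - n_male))

    rows, gt_rows = [], []
    sid = 0
    for gi, gname in enumerate(groups):
        # age/sex matched: the second group re-uses the first group's draws
        ages = np.clip(base_age + (r_demo.normal(0, 0.25, n_per_group) if gi else 0.0), lo, hi)
        cap = r_demo.normal(eff.capacity_mean[gi], eff.capacity_sd[gi], n_per_group)
        for i in range(n_per_group):
            sid += 1
            subject = f"S{sid:03d}"
            row = dict(subject=subject, group=gname, age=float(ages[i]), sex=sex[i],
                       capacity=float(np.clip(cap[i], 1.0, 6.0)))
            for score, (m1, s1, m2, s2) in eff.scores.items():
                m, s = (m1, s1) if gi == 0 else (m2, s2)
                row[score] = float(r_scores.normal(m, s))
            rows.append(row)

            amp_int = r_erp.normal(0, eff.amp_intercept_sd)
            lat_int = r_erp.normal(0, eff.latency_intercept_sd)
            g_amp = eff.group_amp_shift_uv if gi == 0 else 0.0
            g_lat1 = eff.group_latency_shift_1back_ms if gi == 0 else 0.0
            g_lat2 = eff.group_latency_shift_2back_ms if gi == 0 else 0.0
            amp1 = eff.amp_1back_uv + g_amp + amp_int + r_erp.normal(0, eff.amp_condition_sd)
            amp2 = eff.amp_2back_uv + g_amp + amp_int + r_erp.normal(0, eff.amp_condition_sd)
            lat1 = (eff.latency_1back_ms + g_lat1 + lat_int
                    + r_erp.normal(0, eff.latency_condition_sd))
            lat2 = (eff.latency_1back_ms + eff.load_latency_shift_ms + g_lat2 + lat_int
                    + r_erp.normal(0, eff.latency_condition_sd))
            n_bad = min(int(r_art.poisson(0.6)), 3)
            bad = list(r_art.choice(_BAD_CANDIDATES, size=n_bad, replace=False))
            gt_rows.append(dict(
                subject=subject, group=gname,
                amp_1back_uv=float(max(amp1, 0.5)), amp_2back_uv=float(max(amp2, 0.5)),
                lat_1back_ms=float(np.clip(lat1, 320.0, 680.0)),
                lat_2back_ms=float(np.clip(lat2, 320.0, 680.0)),
                nontarget_amp_frac=eff.nontarget_amp_frac,
                topography_center="Pz",
                blink_rate_per_min=float(r_art.uniform(6.0, 18.0)),
                bad_channels=",".join(bad),
                capacity=row["capacity"],
                seed=int(root.entropy % (2**31)) ^ sid,
            ))
    subjects = pd.DataFrame(rows)
    ground_truth = pd.DataFrame(gt_rows)
    return subjects, ground_truth


#: channels eligible as random "bad" channels (never ROI members, EOG or Pz)
_BAD_CANDIDATES = ["TP7", "TP8", "FT7", "FT8", "T7", "T8", "Iz", "Fpz", "AF7", "AF8"]


# --------------------------------------------------------------------------- #
# continuous recording


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int, sfreq: float,
                rms: float) -> np.ndarray:
    """1/f-spectrum Gaussian noise, per channel, normalized to the target RMS."""
    if rms == 0:
        return np.zeros((n_ch, n_samp))
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n_samp, axis=1)
    pink *= rms / pink.std(axis=1, keepdims=True)
    return pink


def _gaussian_pulse(t_ms: np.ndarray, center_ms: float, sigma_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center_ms) / sigma_ms) ** 2)


def _spatial_weights(montage: Montage, center: str, sigma_rad: float,
                     labels) -> np.ndarray:
    d = montage.geodesic_distances(center, labels)
    return np.exp(-0.5 * (d / sigma_rad) ** 2)


def simulate_recording(
    ground_truth_row,
    sequences: list[TrialSequence],
    montage: Montage | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    sfreq: float = SFREQ,
    inter_block_gap_s: float = 5.0,
    observer: CapacityLimitedObserver | None = None,
) -> ContinuousRecording:
    """Build one subject's continuous EEG session from ground truth + sequences.

    ``sequences`` is the ordered list of task blocks (e.g. the fixed 1,2,2,1
    design).  Behavioral responses are simulated with a capacity-limited
    observer (capacity from the ground-truth row unless ``observer`` is
    given), so event metadata carries per-trial correctness and RT.  The
    P300 pulse is injected at each stimulus onset with the subject's true
    amplitude/latency for that load level, scaled down for non-targets.
    """
    gt = dict(ground_truth_row)
    montage = montage or make_montage()
    noise = noise or NoiseConfig()
    root = np.random.SeedSequence(int(seed))
    # sub-streams: responses, background, alpha, trial jitter, blinks, saccades, bad
    r_resp, r_bg, r_alpha, r_trial, r_blink, r_sacc, r_bad = [
        np.random.default_rng(s) for s in root.spawn(7)
    ]
    observer = observer or EEGTaskObserver(capacity=float(gt.get("capacity", 3.2)))

    ch_names = list(montage.labels)
    scalp = list(montage.scalp_labels)
    n_scalp = len(scalp)

    # lay out blocks on the session timeline
    onset_rows = []
    t0 = inter_block_gap_s * 1000.0
    for bi, seq in enumerate(sequences):
        onsets = seq.onsets_ms(t0)
        pressed, rts = observer.respond(seq, r_resp)
        tgt = seq.is_target
        correct = np.where(tgt, pressed, ~pressed)
        for k, trial in enumerate(seq.trials):
            onset_rows.append(dict(
                sample=int(round(onsets[k] * sfreq / 1000.0)),
                onset_ms=float(onsets[k]), block=bi, level=seq.level,
                position=trial.position, stimulus=trial.stimulus,
                is_target=bool(tgt[k]), response=bool(pressed[k]),
                correct=bool(correct[k]),
                rt_ms=float(rts[k]) if np.isfinite(rts[k]) else np.nan,
            ))
        t0 = onsets[-1] + 2500.0 + inter_block_gap_s * 1000.0
    events = pd.DataFrame(onset_rows)
    n_samp = int(round((t0 + 2.0 * 1000.0) * sfreq / 1000.0))
    t_ms = 1000.0 * np.arange(n_samp) / sfreq

    data = np.zeros((len(ch_names), n_samp))
    scalp_idx = [ch_names.index(c) for c in scalp]

    # background: spatially correlated 1/f sources (volume-conduction-like
    # smooth fields) + independent per-channel sensor noise + shared alpha
    if noise.background_rms_uv > 0:
        pos = montage.position_matrix(scalp)
        centers = r_bg.standard_normal((noise.n_noise_sources, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        ang = np.arccos(np.clip(pos @ centers.T, -1.0, 1.0))  # scalp x sources
        W = np.exp(-0.5 * (ang / 0.6) ** 2)
        src = _pink_noise(r_bg, noise.n_noise_sources, n_samp, sfreq, 1.0)
        bg = W @ src
        shared_rms = noise.background_rms_uv * np.sqrt(1.0 - noise.sensor_noise_frac**2)
        bg *= shared_rms / max(bg.std(axis=1).mean(), 1e-12)
        data[scalp_idx, :] += bg
        data[scalp_idx, :] += _pink_noise(
            r_bg, n_scalp, n_samp, sfreq,
            noise.background_rms_uv * noise.sensor_noise_frac,
        )
    for aux in ("VEOG", "HEOG", "M1", "M2"):
        data[ch_names.index(aux)] += _pink_noise(
            r_bg, 1, n_samp, sfreq, noise.background_rms_uv * 0.5
        )[0]
    if noise.alpha_rms_uv > 0:
        from scipy import signal as _sig

        src = _sig.sosfiltfilt(
            _sig.butter(4, [8.0 / (sfreq / 2), 12.0 / (sfreq / 2)], "bandpass", output="sos"),
            r_alpha.standard_normal(n_samp),
        )
        src *= noise.alpha_rms_uv / src.std()
        w = _spatial_weights(montage, "POz", 0.7, scalp)
        data[scalp_idx, :] += np.outer(w, src)

    # P300 pulses
    p300_w = _spatial_weights(montage, str(gt.get("topography_center", "Pz")),
                              P300_SPATIAL_SIGMA_RAD, scalp)
    for row in onset_rows:
        level = row["level"]
        amp = float(gt[f"amp_{level}back_uv"]) / PULSE_WINDOW_GAIN
        lat = float(gt[f"lat_{level}back_ms"])
        if not row["is_target"]:
            amp *= float(gt.get("nontarget_amp_frac", 0.35))
        if noise.trial_amp_jitter > 0:
            amp *= max(1.0 + r_trial.normal(0, noise.trial_amp_jitter), 0.0)
        s0 = row["sample"]
        lo = max(s0 + int((lat - 4 * P300_SIGMA_MS) * sfreq / 1000.0), 0)
        hi = min(s0 + int((lat + 4 * P300_SIGMA_MS) * sfreq / 1000.0), n_samp)
        pulse = amp * _gaussian_pulse(t_ms[lo:hi], t_ms[s0] + lat, P300_SIGMA_MS)
        data[scalp_idx, lo:hi] += np.outer(p300_w, pulse)

    # ocular artifacts
    if noise.include_artifacts and noise.blink_rate_per_min > 0:
        rate = float(gt.get("blink_rate_per_min", noise.blink_rate_per_min))
        n_blinks = r_blink.poisson(rate * n_samp / sfreq / 60.0)
        centers = np.sort(r_blink.uniform(0.5, n_samp / sfreq - 0.5, n_blinks)) * 1000.0
        keep = np.concatenate([[True], np.diff(centers) > 400.0]) if n_blinks else []
        blink_w = _spatial_weights(montage, "Fpz", BLINK_SPATIAL_SIGMA_RAD, scalp)
        veog_i = ch_names.index("VEOG")
        for c in centers[keep] if n_blinks else []:
            amp = noise.blink_amp_uv * max(r_blink.normal(1.0, 0.1), 0.3)
            lo = max(int((c - 4 * noise.blink_width_ms) * sfreq / 1000.0), 0)
            hi = min(int((c + 4 * noise.blink_width_ms) * sfreq / 1000.0), n_samp)
            pulse = _gaussian_pulse(t_ms[lo:hi], c, noise.blink_width_ms)
            data[veog_i, lo:hi] += amp * pulse
            data[scalp_idx, lo:hi] += np.outer(noise.blink_frontal_gain * amp * blink_w, pulse)

    if noise.include_artifacts and noise.saccade_rate_per_min > 0:
        heog_i = ch_names.index("HEOG")
        n_sacc = r_sacc.poisson(noise.saccade_rate_per_min * n_samp / sfreq / 60.0)
        for _ in range(n_sacc):
            start = r_sacc.integers(0, max(n_samp - 1, 1))
            dur = int(r_sacc.uniform(0.2, 0.6) * sfreq)
            amp = noise.saccade_amp_uv * r_sacc.choice([-1.0, 1.0])
            data[heog_i, start : min(start + dur, n_samp)] += amp

    bad = [c for c in str(gt.get("bad_channels", "")).split(",") if c]
    if noise.include_artifacts and bad:
        for c in bad:
            i = ch_names.index(c)
            data[i] = r_bad.standard_normal(n_samp) * noise.bad_channel_rms_uv

    return ContinuousRecording(sfreq, ch_names, data, events)


def simulate_eeg_session(
    ground_truth_row,
    montage: Montage | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    blocks: tuple[int, ...] = (1, 2, 2, 1),
    sequence_config: EEGSequenceConfig | None = None,
) -> ContinuousRecording:
    """The fixed-order EEG n-back session (default blocks 1,2,2,1)."""
    root = np.random.SeedSequence(int(seed))
    seq_rngs = [np.random.default_rng(s) for s in root.spawn(len(blocks) + 1)]
    cfg = sequence_config or EEGSequenceConfig()
    sequences = [generate_sequence(b, "eeg", cfg, seq_rngs[i]) for i, b in enumerate(blocks)]
    return simulate_recording(ground_truth_row, sequences, montage, noise,
                              seed=int(root.generate_state(1)[0] % (2**31)))


def simulate_behavioral_sessions(
    subjects: pd.DataFrame,
    rules: StaircaseRules | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the adaptive staircase for every subject (capacity-limited observer).

    Returns one row per subject with the achieved mean n-back and mean RT -
    the behavioral performance measures entering the Kaplan-Meier analysis.
    """
    rules = rules or StaircaseRules()
    root = np.random.SeedSequence(int(seed))
    out = []
    for rng, (_, row) in zip(
        [np.random.default_rng(s) for s in root.spawn(len(subjects))], subjects.iterrows()
    ):
        obs = CapacityLimitedObserver(capacity=float(row["capacity"]))
        session = run_staircase(obs, rules, rng)
        out.append(dict(subject=row["subject"], group=row["group"],
                        mean_nback=session.mean_nback, mean_rt_ms=session.mean_rt_ms,
                        n_blocks=len(session.blocks), termination=session.termination))
    return pd.DataFrame(out)


# --------------------------------------------------------------------------- #
# measurement-level evoked synthesis (for parameter-recovery studies)


def synthesize_evoked(
    ground_truth_row,
    level: int,
    n_trials: int = 40,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    sfreq: float = 200.0,
    tmin_ms: float = -100.0,
    tmax_ms: float = 900.0,
):
    """Average of ``n_trials`` synthetic single-trial Pz epochs for one condition.

    A fast stand-in for the full continuous pipeline when only the measured
    Pz waveform matters (e.g. power studies over many replicates): each trial
    is the subject's true P300 pulse plus 1/f noise low-passed at 30 Hz,
    baseline-corrected on -100..0 ms, then averaged.
    """
    from scipy import signal as _sig

    from .erp import Evoked

    gt = dict(ground_truth_row)
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(int(seed))
    n = int(round((tmax_ms - tmin_ms) * sfreq / 1000.0))
    t = tmin_ms + 1000.0 * np.arange(n) / sfreq
    amp = float(gt[f"amp_{level}back_uv"]) / PULSE_WINDOW_GAIN
    lat = float(gt[f"lat_{level}back_ms"])
    trials = np.zeros((n_trials, n))
    if noise.background_rms_uv > 0:
        pink = _pink_noise(rng, n_trials, n, sfreq, noise.background_rms_uv)
        sos = _sig.butter(4, 30.0 / (sfreq / 2), "lowpass", output="sos")
        trials += _sig.sosfiltfilt(sos, pink, axis=1)
    amps = amp * np.clip(1.0 + rng.normal(0, noise.trial_amp_jitter, n_trials), 0.0, None)
    trials += amps[:, None] * _gaussian_pulse(t, lat, P300_SIGMA_MS)[None, :]
    base = (t >= -100.0) & (t < 0.0)
    trials -= trials[:, base].mean(axis=1, keepdims=True)
    return Evoked(condition=f"{level}back/target", ch_names=["Pz"],
                  data=trials.mean(axis=0)[None, :], times_ms=t, n_trials=n_trials)
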