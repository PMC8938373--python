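import numpy as np
import pandas as pd
import pytest

from nbackerp import erp, preprocess as pp
from nbackerp.ica import detect_blinks_and_topography
from nbackerp.montage import make_montage
from nbackerp.simulate import (
    NoiseConfig,
    P300_SIGMA_MS,
    PULSE_WINDOW_GAIN,
    null_effects,
    noiseless,
    simulate_behavioral_sessions,
    simulate_cohort,
    simulate_recording,
)
from nbackerp.stats import two_sample_t
from nbackerp.task import EEGSequenceConfig, generate_sequence


class TestCohort:
    def test_shape_and_group_sizes(self, small_cohort):
        subjects, gt = small_cohort
        assert len(subjects) == 8
        assert subjects.groupby("group").size().tolist() == [4, 4]
        assert len(gt) == 8

    def test_default_cohort_is_16_per_group(self):
        subjects, _ = simulate_cohort(seed=0)
        assert len(subjects) == 32
        assert (subjects.groupby("group").size() == 16).all()

    def test_ages_in_range_no_missing(self, small_cohort):
        subjects, gt = small_cohort
        assert subjects["age"].between(11, 17).all()
        assert subjects[["group", "age", "sex"]].notna().all().all()
        assert np.isfinite(gt[["amp_1back_uv", "amp_2back_uv"]].to_numpy()).all()
        assert gt["lat_1back_ms"].between(-100, 900).all()

    def test_same_seed_is_bit_identical(self):
        a_subj, a_gt = simulate_cohort(5, seed=99)
        b_subj, b_gt = simulate_cohort(5, seed=99)
        pd.testing.assert_frame_equal(a_subj, b_subj)
        pd.testing.assert_frame_equal(a_gt, b_gt)

    def test_null_effects_calibrated(self):
        """With zero group differences, group t-tests stay non-significant at
        roughly the nominal rate."""
        eff = null_effects()
        hits = 0
        for seed in range(100):
            subjects, _ = simulate_cohort(16, eff, seed=seed)
            a = subjects.loc[subjects["group"] == "nf1", "digit_span_forward"]
            b = subjects.loc[subjects["group"] == "control", "digit_span_forward"]
            hits += two_sample_t(a, b).p < 0.05
        assert hits <= 10

    def test_malformed_effect_config_rejected(self):
        eff = null_effects()
        eff.scores["corsi_span"] = (4.0, 1.0)
        with pytest.raises(ValueError):
            simulate_cohort(4, eff, seed=0)
        with pytest.raises(ValueError):
            simulate_cohort(1, seed=0)


@pytest.fixture(scope="module")
def montage_mod():
    return make_montage()


def _sequences(n_trials=40, n_targets=10, seed=0):
    cfg = EEGSequenceConfig(n_trials=n_trials, n_targets=n_targets)
    return [
        generate_sequence(1, "eeg", cfg, seed=seed * 7 + 1),
        generate_sequence(2, "eeg", cfg, seed=seed * 7 + 2),
    ]


class TestRecording:
    def test_same_seed_bit_identical(self, small_cohort, montage_mod):
        _, gt = small_cohort
        row = dict(gt.iloc[0])
        a = simulate_recording(row, _sequences(), montage_mod, NoiseConfig(), seed=4)
        b = simulate_recording(row, _sequences(), montage_mod, NoiseConfig(), seed=4)
        assert np.array_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_noiseless_pipeline_recovers_injected_pulse(self, small_cohort, montage_mod):
        """Zero noise and no artifacts: epoching + averaging returns the
        injected P300 waveform at Pz, and the measured latency/amplitude match
        the ground truth."""
        _, gt = small_cohort
        row = dict(gt.iloc[1])
        row["bad_channels"] = ""
        rec = simulate_recording(row, _sequences(), montage_mod, noiseless(), seed=0)
        rec = pp.rereference(rec)
        ep = pp.epoch_baseline(rec, (-100.0, 900.0), (-100.0, 0.0))
        mask = ep.metadata["is_target"].to_numpy() & (ep.metadata["level"] == 1).to_numpy()
        ev = erp.average_evoked(ep, mask=mask)
        t = ev.times_ms
        lat, amp = row["lat_1back_ms"], row["amp_1back_uv"]
        expect = amp / PULSE_WINDOW_GAIN * np.exp(-0.5 * ((t - lat) / P300_SIGMA_MS) ** 2)
        # compare on the pulse's support (the generator truncates at 4 sigma)
        core = np.abs(t - lat) <= 3.8 * P300_SIGMA_MS
        assert np.abs(ev.channel("Pz") - expect)[core].max() < 1e-9
        # outside the support (incl. the baseline window) the signal is exactly 0
        far = np.abs(t - lat) > 4.1 * P300_SIGMA_MS
        assert np.abs(ev.channel("Pz"))[far].max() == 0.0
        # peak sample within one sample period of the injected latency
        assert abs(t[np.argmax(ev.channel("Pz"))] - lat) <= 1000.0 / rec.sfreq
        # window-mean amplitude recovers the ground-truth value closely
        # (exact up to the subject's latency offset from the window center)
        assert erp.window_amplitude(ev, "Pz", (300.0, 700.0)) == pytest.approx(amp, rel=0.05)

    def test_target_nontarget_difference_peaks_at_pz(self, montage_mod):
        """Grand average over a few simulated subjects: the maximal
        target-minus-non-target window-mean difference falls on Pz."""
        subjects, gt = simulate_cohort(2, seed=31)
        diffs = []
        for i in range(4):
            row = dict(gt.iloc[i])
            row["bad_channels"] = ""
            rec = simulate_recording(row, _sequences(50, 12, seed=i), montage_mod,
                                     NoiseConfig(), seed=100 + i)
            rec = pp.rereference(rec)
            rec = pp.filter_resample(rec)
            ep = pp.epoch_baseline(rec, (-100.0, 900.0), (-100.0, 0.0))
            ep.data = pp._sos_filter(ep.data, ep.sfreq, "lowpass", 30.0)
            tgt = ep.metadata["is_target"].to_numpy()
            d = erp.difference_wave(erp.average_evoked(ep, mask=tgt),
                                    erp.average_evoked(ep, mask=~tgt))
            diffs.append(d)
        grand = erp.grand_average(diffs)
        scalp = list(montage_mod.scalp_labels)
        wm = [erp.window_amplitude(grand, c, (300.0, 700.0)) for c in scalp]
        assert scalp[int(np.argmax(wm))] == "Pz"

    def test_blink_count_matches_poisson_rate(self, small_cohort, montage_mod):
        """15 blinks/min over ~10 minutes: the detector's count lands within
        3 sigma of the nominal Poisson count."""
        _, gt = small_cohort
        row = dict(gt.iloc[0])
        row["blink_rate_per_min"] = 15.0
        row["bad_channels"] = ""
        seqs = _sequences(n_trials=115, n_targets=25, seed=3)
        rec = simulate_recording(row, seqs, montage_mod,
                                 NoiseConfig(saccade_rate_per_min=0.0), seed=17,
                                 sfreq=256.0)
        minutes = rec.n_samples / rec.sfreq / 60.0
        assert minutes > 8.0
        res = detect_blinks_and_topography(rec)
        expected = 15.0 * minutes
        assert abs(len(res.events) - expected) < 3.0 * np.sqrt(expected)
        # frontal topography: maximal blink deflection on a prefrontal channel
        scalp = list(montage_mod.scalp_labels)
        assert scalp[int(np.argmax(res.topography))] in {"Fp1", "Fpz", "Fp2"}

    def test_bad_channels_have_inflated_variance(self, small_cohort, montage_mod):
        _, gt = small_cohort
        row = dict(gt.iloc[0])
        row["bad_channels"] = "T8"
        rec = simulate_recording(row, _sequences(), montage_mod, NoiseConfig(), seed=2)
        v = rec.data.var(axis=1)
        assert np.argmax(v[:64]) == rec.ch_names.index("T8")


class TestBehavioralSessions:
    def test_sessions_report_mean_nback_per_subject(self, small_cohort):
        subjects, _ = small_cohort
        out = simulate_behavioral_sessions(subjects, seed=1)
        assert len(out) == len(subjects)
        assert out["mean_nback"].between(1, 9).all()

    def test_higher_capacity_reaches_higher_levels(self):
        subjects = pd.DataFrame({
            "subject": [f"s{i}" for i in range(12)],
            "group": ["lo"] * 6 + ["hi"] * 6,
            "capacity": [1.2] * 6 + [5.0] * 6,
        })
        out = simulate_behavioral_sessions(subjects, seed=0)
        lo = out.loc[out["group"] == "lo", "mean_nback"].mean()
        hi = out.loc[out["group"] == "hi", "mean_nback"].mean()
        assert hi > lo + 1.0
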