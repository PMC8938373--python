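import numpy as np
import pandas as pd
import pytest

from nbackerp.ica import (
    apply_cleaning,
    blink_topography,
    build_cleaning_montage,
    detect_bad_channels,
    detect_blinks,
    fit_ica,
    score_components,
    select_removal,
)
from nbackerp.preprocess import EpochSet


def toy_sources(n=6000, rng=None):
    rng = rng or np.random.default_rng(0)
    return np.vstack([
        np.sign(np.sin(np.arange(n) * 0.071)),
        rng.laplace(size=n),
        np.sin(np.arange(n) * 0.0137) ** 3,
    ])


class TestFitICA:
    def test_known_mixing_recovery(self, rng):
        S = toy_sources(rng=rng)
        A = rng.normal(size=(6, 3))
        model = fit_ica(A @ S, n_components=3, seed=1)
        corr = np.abs(np.corrcoef(np.vstack([model.sources, S]))[:3, 3:])
        # each true source matched by some component up to sign/permutation
        assert (corr.max(axis=0) > 0.99).all()
        ident = model.unmixing @ model.mixing
        assert np.abs(ident - np.eye(3)).max() < 1e-6

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(6, 2000))
        a = fit_ica(X, n_components=4, seed=7)
        b = fit_ica(X, n_components=4, seed=7)
        assert np.array_equal(a.unmixing, b.unmixing)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ica(rng.normal(size=(4, 500)), n_components=7)

    def test_rank_deficiency_reduces_with_warning(self, rng, caplog):
        X = rng.normal(size=(2, 3000))
        X = np.vstack([X, X.sum(axis=0, keepdims=True)])  # rank 2
        with caplog.at_level("WARNING"):
            model = fit_ica(X, n_components=3, seed=0)
        assert model.n_components == 2


class TestBlinkDetection:
    def test_injection_recovery(self, rng):
        fs, ns = 200.0, 20000
        veog = rng.normal(0, 6, ns)
        truth = np.arange(500, ns - 500, 1900)
        for c in truth:
            veog[c - 80 : c + 80] += 200 * np.exp(-0.5 * (np.arange(-80, 80) / 25.0) ** 2)
        events = detect_blinks(veog, fs)
        assert len(events) == len(truth)
        assert np.abs(events - truth).max() <= 0.020 * fs  # within 20 ms

    def test_flat_veog_gives_no_events(self):
        assert detect_blinks(np.zeros(5000), 200.0).size == 0

    def test_topography_maximal_at_frontal_channels(self, rng):
        fs, ns = 200.0, 10000
        events = np.array([2000, 5000, 8000])
        weights = np.array([1.0, 0.8, 0.2, 0.05])  # "frontal" channels first
        eeg = rng.normal(0, 1, size=(4, ns))
        for c in events:
            pulse = 100 * np.exp(-0.5 * (np.arange(-60, 60) / 20.0) ** 2)
            eeg[:, c - 60 : c + 60] += np.outer(weights, pulse)
        topo = blink_topography(eeg, events, fs)
        assert int(np.argmax(topo)) == 0
        assert topo[0] > topo[2] > topo[3]

    def test_no_fitting_epochs_returns_none(self, rng):
        assert blink_topography(rng.normal(size=(2, 50)), np.array([0]), 200.0) is None


class TestComponentScoring:
    def _scored_model(self, rng, veog_in_data=True):
        n = 8000
        fs = 200.0
        veog = np.zeros(n)
        for c in range(400, n - 400, 900):
            veog[c - 60 : c + 60] += 150 * np.exp(-0.5 * (np.arange(-60, 60) / 20.0) ** 2)
        veog += rng.normal(0, 3, n)
        heog = rng.normal(0, 3, n)
        X = rng.normal(size=(12, n)) * 4
        if veog_in_data:
            w = rng.uniform(0.3, 1.0, 12)
            X += np.outer(w, veog)
        model = fit_ica(X, n_components=8, seed=3)
        score_components(model, veog, heog, None, fs)
        return model

    def test_veog_copy_component_flagged(self, rng):
        model = self._scored_model(rng)
        best = int(np.abs(model.corr["veog"]).argmax())
        assert abs(model.zscores["veog"][best]) > 2.0
        assert model.suspects[best]

    def test_zscores_sum_to_zero(self, rng):
        model = self._scored_model(rng)
        for z in model.zscores.values():
            assert abs(z.sum()) < 1e-9
            assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_equal_correlations_fall_back_to_zero(self):
        from nbackerp.ica import _zscore_across

        notes = []
        z = _zscore_across(np.full(8, 0.3), "veog", notes)
        assert np.allclose(z, 0.0)
        assert notes

    def test_confirmation_floor_blocks_weak_suspects(self, rng):
        model = self._scored_model(rng, veog_in_data=False)
        # without a planted ocular component nothing should pass the raw-
        # correlation confirmation floor, whatever the z outliers do
        removed = select_removal(model, min_abs_corr=0.99)
        assert removed == []

    def test_operator_override_logged(self, rng):
        model = self._scored_model(rng)
        removed = select_removal(model, override=[5])
        assert removed == [5]


class TestBadChannels:
    def test_injected_noisy_channel_found(self, rng):
        X = rng.normal(size=(16, 4000))
        X[11] *= 10.0
        assert detect_bad_channels(X) == ["ch11"]

    def test_false_positive_rate_under_homogeneous_noise(self):
        hits = 0
        for seed in range(100):
            X = np.random.default_rng(seed).normal(size=(16, 800))
            hits += bool(detect_bad_channels(X))
        assert hits < 5

    def test_force_list_always_included(self, rng):
        X = rng.normal(size=(4, 500))
        bad = detect_bad_channels(X, force=("ch2",), ch_names=["ch0", "ch1", "ch2", "ch3"])
        assert "ch2" in bad


class TestCleaningMontage:
    def _model(self, montage, rng):
        scalp = list(montage.scalp_labels)
        X = rng.normal(size=(64, 6000))
        return fit_ica(X, n_components=16, seed=0, ch_names=scalp)

    def test_identity_when_nothing_removed(self, montage, rng):
        cm = build_cleaning_montage(self._model(montage, rng), [], montage, [])
        assert np.allclose(cm.composed, np.eye(64))

    def test_removal_matrix_idempotent(self, montage, rng):
        cm = build_cleaning_montage(self._model(montage, rng), [0, 3], montage, [])
        P = cm.removal
        assert np.abs(P @ P - P).max() < 1e-9

    def test_interpolation_rows_sum_to_one(self, montage, rng):
        cm = build_cleaning_montage(self._model(montage, rng), [], montage, ["TP7", "Iz"])
        scalp = list(montage.scalp_labels)
        for c in ("TP7", "Iz"):
            row = cm.interpolation[scalp.index(c)]
            assert row.sum() == pytest.approx(1.0)
            assert row[scalp.index(c)] == 0.0

    def test_smooth_field_interpolation_accuracy(self, montage, rng):
        # noiseless smooth spatial field: interpolation recovers the bad site
        scalp = list(montage.scalp_labels)
        pos = montage.position_matrix()
        field = 10.0 + 5.0 * pos[:, 1] + 3.0 * pos[:, 2]  # smooth over the cap
        model = self._model(montage, rng)
        cm = build_cleaning_montage(model, [], montage, ["CP1"])
        recovered = cm.interpolation @ field
        i = scalp.index("CP1")
        assert recovered[i] == pytest.approx(field[i], rel=0.10)

    def test_all_bad_rejected(self, montage, rng):
        model = self._model(montage, rng)
        with pytest.raises(ValueError):
            build_cleaning_montage(model, [], montage, list(montage.scalp_labels))

    def test_apply_cleaning_preserves_untouched_channels(self, montage, rng):
        model = self._model(montage, rng)
        cm = build_cleaning_montage(model, [], montage, [])
        data = rng.normal(size=(3, 68, 40))
        ep = EpochSet(200.0, list(montage.labels), -100.0, data.copy(),
                      pd.DataFrame({"i": range(3)}))
        out = apply_cleaning(ep, cm)
        assert np.allclose(out.data, data, atol=1e-12)

    def test_removal_projects_out_planted_component(self, montage, rng):
        scalp = list(montage.scalp_labels)
        n = 6000
        blink = np.zeros(n)
        for c in range(300, n - 300, 700):
            blink[c - 50 : c + 50] += 120 * np.exp(-0.5 * (np.arange(-50, 50) / 16.0) ** 2)
        w = np.exp(-0.5 * (montage.geodesic_distances("Fpz") / 0.5) ** 2)
        X = rng.normal(size=(64, n)) * 3 + np.outer(w, blink)
        model = fit_ica(X, n_components=16, seed=2, ch_names=scalp)
        heog = rng.normal(size=n)
        score_components(model, blink, heog, w, 200.0)
        removed = select_removal(model)
        assert removed, "planted blink component must be flagged and confirmed"
        cm = build_cleaning_montage(model, removed, montage, [])
        cleaned = cm.composed @ X
        r = np.corrcoef(cleaned[scalp.index("Fpz")], blink)[0, 1]
        assert abs(r) < 0.05
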