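import numpy as np
import pytest

from pharmaeeg.containers import ArtifactAnnotation
from pharmaeeg.preprocessing import (
    PreprocessingError, bandpass_and_notch, detect_artifacts,
    exclude_reference_and_segment, interpolate_or_exclude, ocular_correction,
    preprocess_recording, repair_bad_channels, resample_to_256,
)
from pharmaeeg.montage import neighbor_adjacency

from conftest import make_recording


def _sine_rec(montage, freq, amp=1.0, fs=512.0, dur=8.0):
    t = np.arange(int(dur * fs)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (29, 1))
    return make_recording(montage, data, fs=fs)


class TestBandpassAndNotch:
    def test_dc_offset_removed(self, montage):
        rec = make_recording(montage, np.full((29, 4096), 100.0), fs=512.0)
        out = bandpass_and_notch(rec)
        assert np.abs(out.data[:29]).max() < 1.0  # < 1% of the 100 uV offset

    def test_midband_sine_passes_unattenuated(self, montage):
        rec = _sine_rec(montage, 10.0)
        out = bandpass_and_notch(rec)
        steady = out.data[0, 1024:-1024]
        assert 0.95 <= np.abs(steady).max() <= 1.05

    def test_50hz_attenuated_by_20db(self, montage):
        rec = _sine_rec(montage, 50.0)
        out = bandpass_and_notch(rec)
        steady = out.data[0, 1024:-1024]
        ratio = np.sqrt(np.mean(steady ** 2)) / np.sqrt(0.5)
        assert 20 * np.log10(1.0 / ratio) >= 20.0

    def test_zero_phase(self, montage):
        rec = _sine_rec(montage, 10.0)
        out = bandpass_and_notch(rec)
        x = rec.data[0, 1024:-1024]
        y = out.data[0, 1024:-1024]
        lags = np.arange(-20, 21)
        xc = [np.dot(x, np.roll(y, k)) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_low_rate_rejected(self, montage):
        rec = make_recording(montage, np.zeros((29, 512)), fs=150.0)
        with pytest.raises(PreprocessingError):
            bandpass_and_notch(rec)


class TestResample:
    def test_length_arithmetic_2500_to_256(self, montage):
        rec = make_recording(montage, np.random.default_rng(0).normal(size=(29, 25000)),
                             fs=2500.0)
        out = resample_to_256(rec)
        assert out.fs == 256.0
        assert abs(out.n_samples - 2560) <= 1

    def test_sine_survives_resampling(self, montage):
        from scipy import signal as spsig

        rec = _sine_rec(montage, 10.0, fs=512.0)
        out = resample_to_256(rec)
        f, p = spsig.periodogram(out.data[0], fs=256.0)
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=0.3)

    def test_high_frequency_component_suppressed(self, montage):
        rec = _sine_rec(montage, 200.0, fs=2500.0, dur=4.0)
        out = resample_to_256(rec)
        # 200 Hz is above the new Nyquist: anti-alias must kill it
        assert np.sqrt(np.mean(out.data[0, 200:-200] ** 2)) < 0.1 * np.sqrt(0.5)

    def test_upsampling_rejected(self, montage):
        rec = make_recording(montage, np.zeros((29, 100)), fs=128.0)
        with pytest.raises(PreprocessingError):
            resample_to_256(rec)


class TestOcularCorrection:
    def test_known_mixing_removed(self, montage):
        rng = np.random.default_rng(4)
        n = 4096
        eog = np.convolve(rng.standard_normal(n), np.ones(40) / 40, mode="same") * 50
        clean = rng.standard_normal((29, n)) * 10
        data = clean + 0.5 * eog
        rec = make_recording(montage, np.vstack([data, eog[None, :]]), fs=256.0)
        out = ocular_correction(rec)
        resid = out.data[:29] - clean
        assert (resid ** 2).sum() < 0.1 * ((0.5 * eog) ** 2).sum() * 29

    def test_uncorrelated_eog_changes_little(self, montage):
        rng = np.random.default_rng(5)
        n = 4096
        data = rng.standard_normal((29, n)) * 10
        eog = rng.standard_normal(n) * 50
        rec = make_recording(montage, np.vstack([data, eog[None, :]]), fs=256.0)
        out = ocular_correction(rec)
        change = np.sqrt(np.mean((out.data[:29] - data) ** 2))
        assert change < 0.05 * np.sqrt(np.mean(data ** 2))

    def test_zero_eog_is_identity(self, montage):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((29, 1024))
        rec = make_recording(montage, data, fs=256.0)  # EOG row is zeros
        out = ocular_correction(rec)
        np.testing.assert_array_equal(out.data[:29], data)

    def test_missing_eog_channel_rejected(self, montage):
        rec = make_recording(montage, np.zeros((29, 256)), fs=256.0, with_eog=False)
        with pytest.raises(PreprocessingError):
            ocular_correction(rec)


class TestDetectArtifacts:
    def _quiet(self, montage, n=2560, fs=256.0, seed=0):
        """Low-amplitude noise that trips none of the three criteria."""
        rng = np.random.default_rng(seed)
        base = np.cumsum(rng.standard_normal((29, n)), axis=1)
        base = base - np.linspace(base[:, 0], base[:, -1], n).T
        base = 3.0 * base / np.abs(base).max()
        t = np.arange(n) / fs
        base += 10.0 * np.sin(2 * np.pi * 10 * t + rng.uniform(0, 6, (29, 1)))
        return make_recording(montage, base, fs=fs)

    def test_instantaneous_step_flags_gradient_and_amplitude(self, montage):
        rec = self._quiet(montage)
        i = rec.labels.index("Cz")
        rec.data[i, 1000:] += 300.0
        anns = detect_artifacts(rec)
        reasons = {a.reason for a in anns if "Cz" in a.channels
                   and a.start <= 1000 < a.end}
        assert {"gradient", "amplitude"} <= reasons

    def test_constant_recording_is_flatline_end_to_end(self, montage):
        rec = make_recording(montage, np.full((29, 2560), 5.0), fs=256.0)
        anns = detect_artifacts(rec)
        flt = [a for a in anns if a.reason == "flatline"]
        assert len(flt) == 29
        assert all(a.start == 0 and a.end == 2560 for a in flt)

    def test_moderate_sine_is_clean(self, montage):
        # 30 uV at 10 Hz: gradient ~1.9 uV/ms, 200-ms range 60 uV,
        # 100-ms range >= 30 uV -- all three criteria pass
        t = np.arange(2560) / 256.0
        data = np.tile(30.0 * np.sin(2 * np.pi * 10 * t), (29, 1))
        rec = make_recording(montage, data, fs=256.0)
        assert detect_artifacts(rec) == []

    def test_detector_is_translation_equivariant(self, montage):
        shift = 256
        rec1 = self._quiet(montage, seed=1)
        rec2 = self._quiet(montage, seed=1)
        i = rec1.labels.index("Pz")
        rec1.data[i, 1000:1100] += 300.0
        rec2.data[i, 1000 + shift:1100 + shift] += 300.0
        a1 = [a for a in detect_artifacts(rec1) if "Pz" in a.channels]
        a2 = [a for a in detect_artifacts(rec2) if "Pz" in a.channels]
        assert [(a.start + shift, min(a.end + shift, 2560), a.reason) for a in a1] \
            == [(a.start, a.end, a.reason) for a in a2]


class TestRepairBadChannels:
    def test_mean_of_constant_neighbors(self, montage):
        adj = neighbor_adjacency(montage.labels)
        data = np.zeros((29, 256))
        nbs = adj["Cz"]
        for k, nb in enumerate(nbs):
            data[montage.labels.index(nb)] = 1.0 if k % 2 == 0 else 3.0
        data[montage.labels.index("Cz")] = 99.0
        rec = make_recording(montage, data, fs=256.0)
        out = repair_bad_channels(rec, ["Cz"])
        expected = np.mean([1.0 if k % 2 == 0 else 3.0 for k in range(len(nbs))])
        np.testing.assert_allclose(out.channel("Cz"), expected)

    def test_fixed_point_and_idempotence(self, montage):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((29, 512))
        rec = make_recording(montage, data, fs=256.0)
        once = repair_bad_channels(rec, ["F3", "P4"])
        twice = repair_bad_channels(once, ["F3", "P4"])
        np.testing.assert_allclose(once.data, twice.data)

    def test_isolated_channel_rejected(self, montage):
        rec = make_recording(montage, np.zeros((29, 256)), fs=256.0)
        adj = neighbor_adjacency(montage.labels)
        bad = ["Cz"] + list(adj["Cz"])
        with pytest.raises(PreprocessingError):
            repair_bad_channels(rec, bad)


class TestInterpolateOrExclude:
    def test_two_channel_artifact_repaired(self, montage):
        rng = np.random.default_rng(8)
        rec = make_recording(montage, rng.standard_normal((29, 2560)), fs=256.0)
        ann = [ArtifactAnnotation(500, 600, frozenset({"Cz", "Pz"}), "amplitude")]
        out, excl = interpolate_or_exclude(rec, ann)
        assert excl == []
        assert not np.allclose(out.channel("Cz")[500:600], rec.channel("Cz")[500:600])
        np.testing.assert_array_equal(out.channel("Cz")[:500], rec.channel("Cz")[:500])

    def test_three_channel_artifact_excluded(self, montage):
        rng = np.random.default_rng(9)
        rec = make_recording(montage, rng.standard_normal((29, 2560)), fs=256.0)
        ann = [ArtifactAnnotation(500, 600, frozenset({"Cz", "Pz", "Fz"}), "amplitude")]
        out, excl = interpolate_or_exclude(rec, ann)
        assert excl == [(500, 600)]
        np.testing.assert_array_equal(out.data, rec.data)

    def test_empty_annotations_are_a_noop(self, montage):
        rec = make_recording(montage, np.zeros((29, 256)), fs=256.0)
        out, excl = interpolate_or_exclude(rec, [])
        assert excl == []
        np.testing.assert_array_equal(out.data, rec.data)


class TestSegmentation:
    def test_clean_recording_tiles_fully(self, montage):
        rng = np.random.default_rng(10)
        rec = make_recording(montage, rng.standard_normal((29, 300 * 256)), fs=256.0)
        epochs = exclude_reference_and_segment(rec, [])
        assert epochs.n_epochs == 300
        assert len(epochs.labels) == 27

    def test_half_open_tiling_around_exclusion(self, montage):
        # 10 s with [4.0 s, 6.5 s) excluded -> 4-s and 3.5-s segments -> 7 epochs
        rng = np.random.default_rng(11)
        rec = make_recording(montage, rng.standard_normal((29, 2560)), fs=256.0)
        epochs = exclude_reference_and_segment(rec, [(1024, 1664)])
        assert epochs.n_epochs == 7

    def test_common_average_identity(self, montage):
        rng = np.random.default_rng(12)
        rec = make_recording(montage, rng.standard_normal((29, 2560)), fs=256.0)
        epochs = exclude_reference_and_segment(rec, [])
        assert np.abs(epochs.epochs.mean(axis=1)).max() < 1e-9

    def test_too_short_recording_warns_and_returns_empty(self, montage):
        rec = make_recording(montage, np.zeros((29, 100)), fs=256.0)
        with pytest.warns(UserWarning):
            epochs = exclude_reference_and_segment(rec, [])
        assert epochs.n_epochs == 0


def test_full_chain_produces_clean_epochs(montage, short_recording):
    epochs = preprocess_recording(short_recording, condition="rest1")
    assert epochs.n_epochs >= 8
    assert len(epochs.labels) == 27
    assert epochs.fs == 256.0
    assert np.abs(epochs.epochs.mean(axis=1)).max() < 1e-9
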