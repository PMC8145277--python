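import numpy as np
import pytest
from scipy import signal as spsig

from pharmaeeg.montage import posterior_weights
from pharmaeeg.simulate import (
    EEGSimConfig, EffectSpec, SimonConfig, generate_recall_counts,
    generate_recording, generate_simon_session, generate_subject_cohort,
    inject_artifacts,
)
from pharmaeeg.stats import wilcoxon_signed_rank


class TestGenerateRecording:
    def test_same_seed_gives_bit_identical_output(self, montage):
        cfg = EEGSimConfig(duration=4.0, fs_native=512.0, seed=7)
        a = generate_recording(montage, cfg)
        b = generate_recording(montage, cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_pure_alpha_peaks_at_10hz_on_posterior_channels(self, montage):
        cfg = EEGSimConfig(duration=8.0, fs_native=512.0, alpha_amp_uv=30.0,
                           noise_amp_uv=0.0, seed=3,
                           band_levels={}, artifact_rates={})
        rec = generate_recording(montage, cfg)
        for lab in ("O1", "O2", "P3", "P4"):
            f, p = spsig.periodogram(rec.channel(lab), fs=rec.fs)
            assert f[np.argmax(p)] == pytest.approx(10.0, abs=0.5)

    def test_alpha_peak_recovered_from_averaged_periodogram(self, montage):
        # independent periodogram oracle on a long default-config signal
        cfg = EEGSimConfig(duration=60.0, fs_native=512.0, seed=5)
        rec = generate_recording(montage, cfg)
        f, p = spsig.welch(rec.channel("O1"), fs=rec.fs, nperseg=2048)
        band = (f >= 6) & (f <= 14)
        assert f[band][np.argmax(p[band])] == pytest.approx(cfg.alpha_peak_hz, abs=0.5)

    def test_amplitude_scales_with_posterior_weighting(self, montage):
        cfg = EEGSimConfig(duration=8.0, fs_native=512.0, alpha_amp_uv=30.0,
                           noise_amp_uv=0.0, seed=3, band_levels={})
        rec = generate_recording(montage, cfg)
        w = dict(zip(montage.labels, posterior_weights(montage)))
        assert rec.channel("O1").std() > 2.0 * rec.channel("Fp1").std()
        assert w["O1"] > 2.0 * w["Fp1"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EEGSimConfig(duration=-1.0)
        with pytest.raises(ValueError):
            EEGSimConfig(fs_native=128.0)
        with pytest.raises(ValueError):
            EEGSimConfig(artifact_rates={"blink": -1.0})


class TestInjectArtifacts:
    def test_zero_rates_are_a_noop(self, montage, short_recording):
        cfg = EEGSimConfig(duration=10.0, fs_native=512.0, seed=101,
                           artifact_rates={k: 0.0 for k in ("blink", "muscle", "step", "flatline")})
        out, truth = inject_artifacts(short_recording, cfg)
        assert truth == []
        np.testing.assert_array_equal(out.data, short_recording.data)

    def test_step_violates_amplitude_criterion(self, montage):
        # a 300 uV offset must exceed the 200 uV / 200 ms bound at the edge
        cfg = EEGSimConfig(duration=60.0, fs_native=512.0, seed=8,
                           artifact_rates={"blink": 0, "muscle": 0, "step": 2.0, "flatline": 0})
        rec = generate_recording(montage, cfg)
        out, truth = inject_artifacts(rec, cfg)
        steps = [t for t in truth if t.kind == "step"]
        assert steps
        fs = rec.fs
        w = int(round(0.2 * fs))
        for ev in steps:
            for lab in ev.channels:
                seg = out.channel(lab)[max(0, ev.start - w): ev.end + w]
                assert seg.max() - seg.min() > 200.0

    def test_flatline_violates_low_difference_criterion(self, montage):
        cfg = EEGSimConfig(duration=60.0, fs_native=512.0, seed=9,
                           artifact_rates={"blink": 0, "muscle": 0, "step": 0, "flatline": 2.0})
        rec = generate_recording(montage, cfg)
        out, truth = inject_artifacts(rec, cfg)
        flats = [t for t in truth if t.kind == "flatline"]
        assert flats
        w = int(round(0.1 * rec.fs))
        for ev in flats:
            for lab in ev.channels:
                seg = out.channel(lab)[ev.start: ev.start + w]
                assert seg.max() - seg.min() < 0.5

    def test_blink_rides_on_eog_and_frontal_channels(self, montage):
        cfg = EEGSimConfig(duration=60.0, fs_native=512.0, seed=10,
                           artifact_rates={"blink": 3.0, "muscle": 0, "step": 0, "flatline": 0})
        rec = generate_recording(montage, cfg)
        out, truth = inject_artifacts(rec, cfg)
        blinks = [t for t in truth if t.kind == "blink"]
        assert blinks
        ev = blinks[0]
        assert montage.eog_label in ev.channels
        added = out.data - rec.data
        i_fp1 = rec.labels.index("Fp1")
        i_o1 = rec.labels.index("O1")
        assert np.abs(added[i_fp1, ev.start:ev.end]).max() > \
            np.abs(added[i_o1, ev.start:ev.end]).max()

    def test_excessive_rates_rejected(self, montage, short_recording):
        cfg = EEGSimConfig(duration=10.0, fs_native=512.0, seed=1,
                           artifact_rates={"flatline": 200.0})
        with pytest.raises(ValueError, match="exceed"):
            inject_artifacts(short_recording, cfg)


class TestCohort:
    def test_same_master_seed_gives_identical_cohort(self):
        cfg = EEGSimConfig(duration=2.0, fs_native=512.0, seed=42)
        a = generate_subject_cohort(2, [], cfg, conditions=("rest1",), inject=False)
        b = generate_subject_cohort(2, [], cfg, conditions=("rest1",), inject=False)
        np.testing.assert_array_equal(
            a[0].recordings["rest1"]["baseline"].data,
            b[0].recordings["rest1"]["baseline"].data)

    def test_adding_subjects_preserves_earlier_streams(self):
        cfg = EEGSimConfig(duration=2.0, fs_native=512.0, seed=42)
        small = generate_subject_cohort(2, [], cfg, conditions=("rest1",), inject=False)
        large = generate_subject_cohort(3, [], cfg, conditions=("rest1",), inject=False)
        np.testing.assert_array_equal(
            small[1].recordings["rest1"]["followup"].data,
            large[1].recordings["rest1"]["followup"].data)

    def test_null_cohort_has_balanced_paired_differences(self):
        # Monte-Carlo oracle under the null: variance differences across
        # sessions should be centred on zero over 20 subjects
        cfg = EEGSimConfig(duration=2.0, fs_native=512.0, seed=11)
        cohort = generate_subject_cohort(20, [], cfg, conditions=("rest1",), inject=False)
        diffs = []
        for subj in cohort:
            b = subj.recordings["rest1"]["baseline"].data.var(axis=1).mean()
            f = subj.recordings["rest1"]["followup"].data.var(axis=1).mean()
            diffs.append(np.log(f) - np.log(b))
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 2 * se + 1e-12

    def test_activity_effect_raises_variance_on_target_group(self):
        group = ("Cz", "C3", "C4")
        eff = EffectSpec("hjorth_activity", group, direction=1, magnitude=0.5)
        cfg = EEGSimConfig(duration=2.0, fs_native=512.0, seed=13)
        cohort = generate_subject_cohort(6, [eff], cfg, conditions=("rest1",), inject=False)
        ratios = []
        for subj in cohort:
            base = subj.recordings["rest1"]["baseline"]
            foll = subj.recordings["rest1"]["followup"]
            for lab in group:
                ratios.append(foll.channel(lab).var() / base.channel(lab).var())
        assert np.median(ratios) > 1.2

    def test_empty_condition_list_rejected(self):
        cfg = EEGSimConfig(duration=2.0, fs_native=512.0, seed=1)
        with pytest.raises(ValueError):
            generate_subject_cohort(2, [], cfg, conditions=())

    def test_effect_spec_validation(self):
        with pytest.raises(ValueError):
            EffectSpec("not_a_feature", ("Cz",), 1, 0.1)
        with pytest.raises(ValueError):
            EffectSpec("entropy", (), 1, 0.1)
        with pytest.raises(ValueError):
            EffectSpec("entropy", ("NoSuchSite",), 1, 0.1)
        with pytest.raises(ValueError):
            EffectSpec("power", ("Cz",), 1, 0.1)  # band required


class TestSimonTask:
    def test_default_session_structure(self):
        tab = generate_simon_session(SimonConfig(seed=1))
        assert len(tab) == 400
        assert tab.block.nunique() == 4
        counts = tab.groupby("block").condition.value_counts()
        for b in range(4):
            assert counts[b]["congruent"] == 60
            assert counts[b]["incongruent"] == 40

    def test_congruency_effect_matches_target_in_large_sample(self):
        cfg = SimonConfig(n_trials=10000, block_size=100,
                          congruency_effect_ms=48.0, seed=2)
        tab = generate_simon_session(cfg)
        med = tab.groupby("condition").rt_ms.median()
        assert med["incongruent"] - med["congruent"] == pytest.approx(48.0, abs=5.0)

    def test_randomised_order_within_block(self):
        tab = generate_simon_session(SimonConfig(seed=3))
        first_block = tab[tab.block == 0].condition.to_numpy()
        assert len(set(first_block[:20])) == 2  # not sorted runs

    def test_infeasible_proportion_rejected(self):
        with pytest.raises(ValueError):
            SimonConfig(p_congruent=0.615)
        with pytest.raises(ValueError):
            SimonConfig(n_trials=350, block_size=100)

    def test_determinism(self):
        a = generate_simon_session(SimonConfig(seed=5))
        b = generate_simon_session(SimonConfig(seed=5))
        assert a.equals(b)


class TestRecallCounts:
    def test_counts_bounded_by_item_total(self):
        tab = generate_recall_counts("wp", 50, 60, seed=1)
        assert tab.recall_count.between(0, 60).all()

    def test_same_seed_gives_identical_table(self):
        a = generate_recall_counts("vr", 12, 40, seed=9)
        b = generate_recall_counts("vr", 12, 40, seed=9)
        assert a.equals(b)

    def test_null_effect_rarely_significant(self):
        # type-I-error simulation: Wilcoxon on 50 pairs, no session effect
        hits = 0
        for i in range(100):
            tab = generate_recall_counts("wp", 50, 60, effect=0.0, seed=1000 + i)
            piv = tab.pivot(index="subject", columns="session", values="recall_count")
            res = wilcoxon_signed_rank(piv["baseline"].to_numpy(),
                                       piv["followup"].to_numpy())
            if res.p < 0.05:
                hits += 1
        assert hits <= 10
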