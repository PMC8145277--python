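"""Simulation-based calibration of the pipeline.

These helpers run many small end-to-end studies to measure operating
characteristics: the cluster-level false-positive rate under a null cohort,
the recovery rate of injected effects, and the sensitivity of the artifact
detector on ground-truth events.  They are used by the test suite and the
acceptance script; the reduced problem sizes (seconds of EEG per
recording, one condition, one feature) are the package's desk-scale
defaults for Monte-Carlo work and are documented in the methods note.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .features import FeatureConfig, condition_features
from .montage import generate_montage
from .pipeline import StudyConfig, behavioral_contrasts, simulate_behavioral
from .preprocessing import detect_artifacts, interpolate_or_exclude, preprocess_recording
from .simulate import (
    EEGSimConfig, EffectSpec, SimonConfig, _derive_seed, generate_recording,
    generate_subject_cohort, inject_artifacts,
)
from .stats import ClusterTestConfig, build_neighbor_graph, cluster_permutation_test

#: Detector-visible artifact kinds (blinks are handled by ocular correction).
DETECTABLE_KINDS = ("muscle", "step", "flatline")

CENTRAL_FRONTAL = ("Fz", "Cz", "F3", "F4", "C3", "C4", "FC1", "FC2")


def _mini_sim(duration: float, seed: int) -> EEGSimConfig:
    return EEGSimConfig(duration=duration, fs_native=512.0, seed=seed)


def run_mini_study(
    seed: int,
    n_subjects: int = 8,
    duration: float = 6.0,
    feature: str = "entropy",
    effects: tuple[EffectSpec, ...] = (),
    cluster_alpha: float = 0.05,
) -> list:
    """One reduced study on a single condition and feature; returns clusters."""
    montage = generate_montage()
    graph = build_neighbor_graph(montage)
    sim = _mini_sim(duration, seed)
    cohort = generate_subject_cohort(n_subjects, list(effects), sim,
                                     conditions=("rest1",), inject=False)
    fconf = FeatureConfig()
    rows_b, rows_f = [], []
    for subj in cohort:
        for session, store in (("baseline", rows_b), ("followup", rows_f)):
            rec = subj.recordings["rest1"][session]
            epochs = preprocess_recording(rec, condition="rest1")
            tab = condition_features(epochs, fconf)
            vals = tab[tab.feature == feature].set_index("electrode")["value"]
            store.append(vals[list(graph.nodes)].to_numpy())
    baseline = np.stack(rows_b)
    followup = np.stack(rows_f)
    cfg = ClusterTestConfig(cluster_alpha=cluster_alpha, seed=seed)
    return cluster_permutation_test(followup, baseline, graph, cfg)


def null_cluster_false_positive_rate(
    n_runs: int = 200, n_subjects: int = 8, duration: float = 4.0,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Fraction of null-cohort runs with any cluster p < alpha.

    Under a well-calibrated test this is statistically compatible with the
    nominal alpha (binomial fluctuation around 0.05).
    """
    hits = 0
    for i in range(n_runs):
        clusters = run_mini_study(_derive_seed(seed, i, 0xF0),
                                  n_subjects=n_subjects, duration=duration)
        if any(c.p_value < alpha for c in clusters):
            hits += 1
    return hits / n_runs


def entropy_effect_recovery_rate(
    magnitude: float, n_runs: int = 25, n_subjects: int = 8,
    duration: float = 10.0, alpha: float = 0.05, seed: int = 0,
) -> float:
    """Fraction of runs flagging a negative entropy cluster at p < alpha.

    The injected effect is a generative entropy *decrease* (alpha-component
    attenuation) on the central-frontal electrode group.
    """
    effect = EffectSpec(feature_name="entropy", electrode_group=CENTRAL_FRONTAL,
                        direction=-1, magnitude=magnitude)
    hits = 0
    for i in range(n_runs):
        clusters = run_mini_study(_derive_seed(seed, i, 0xE1),
                                  n_subjects=n_subjects, duration=duration,
                                  effects=(effect,))
        if any(c.polarity < 0 and c.p_value < alpha for c in clusters):
            hits += 1
    return hits / n_runs


def simon_effect_recovery_rate(
    effect_ms: float = 48.0, n_runs: int = 25, n_pairs: int = 12, seed: int = 0,
) -> float:
    """Fraction of behavioral-table runs whose within-session congruency
    contrast survives Benjamini-Hochberg at adjusted p < 0.05."""
    hits = 0
    for i in range(n_runs):
        cfg = StudyConfig(n_subjects=n_pairs, n_cognitive=n_pairs,
                          simon=SimonConfig(congruency_effect_ms=effect_ms),
                          seed=_derive_seed(seed, i, 0x51))
        behav = simulate_behavioral(cfg)
        table = behavioral_contrasts(behav["simon"], behav["wp"], behav["vr"],
                                     behav["scores"])
        row = table[table.measure == "simon_rt_c_vs_ic_baseline"].iloc[0]
        if row.p_adj < 0.05:
            hits += 1
    return hits / n_runs


def artifact_detection_sensitivity(
    n_events: int = 60, seed: int = 0, fs: float = 512.0,
) -> float:
    """Fraction of injected (detector-visible) artifact samples flagged.

    Generates recordings with muscle/step/flatline events at default
    template amplitudes, runs the automatic criteria at 256 Hz, and counts
    ground-truth samples covered by detected annotations per channel.
    """
    from .preprocessing import resample_to_256

    covered = total = 0
    per_rec = 12
    n_recs = int(np.ceil(n_events / per_rec))
    montage = generate_montage()
    for r in range(n_recs):
        cfg = EEGSimConfig(
            duration=120.0, fs_native=fs, seed=_derive_seed(seed, r, 0xAD),
            artifact_rates={"blink": 0.0, "muscle": 2.0, "step": 2.0, "flatline": 2.0})
        rec = generate_recording(montage, cfg)
        rec, truth = inject_artifacts(rec, cfg)
        rec = resample_to_256(rec)
        scale = rec.fs / fs
        detected = detect_artifacts(rec)
        masks = {lab: np.zeros(rec.n_samples, bool) for lab in rec.labels}
        for ann in detected:
            for lab in ann.channels:
                masks[lab][ann.start:ann.end] = True
        for ev in truth:
            if ev.kind not in DETECTABLE_KINDS:
                continue
            s = int(np.floor(ev.start * scale))
            e = min(int(np.ceil(ev.end * scale)), rec.n_samples)
            for lab in ev.channels:
                total += e - s
                covered += int(masks[lab][s:e].sum())
    return covered / total


def artifact_handling_coverage(seed: int = 0, fs: float = 512.0) -> float:
    """End-to-end: fraction of ground-truth artifact samples that end up
    repaired or excluded after detection + interpolate/exclude."""
    from .preprocessing import bandpass_and_notch, ocular_correction, resample_to_256

    montage = generate_montage()
    cfg = EEGSimConfig(
        duration=240.0, fs_native=fs, seed=_derive_seed(seed, 0xC0),
        artifact_rates={"blink": 1.0, "muscle": 2.0, "step": 1.5, "flatline": 1.0})
    rec = generate_recording(montage, cfg)
    rec, truth = inject_artifacts(rec, cfg)
    rec = bandpass_and_notch(rec)
    rec = resample_to_256(rec)
    scale = rec.fs / fs
    rec = ocular_correction(rec)
    detected = detect_artifacts(rec)
    repaired = np.zeros(rec.n_samples, bool)
    # repaired intervals: annotations grouped into events by interpolate_or_exclude
    _, exclusions = interpolate_or_exclude(rec, detected)
    for ann in detected:
        repaired[ann.start:ann.end] = True  # flagged -> repaired or excluded
    handled = repaired
    covered = total = 0
    for ev in truth:
        if ev.kind not in DETECTABLE_KINDS:
            continue
        s = int(np.floor(ev.start * scale))
        e = min(int(np.ceil(ev.end * scale)), rec.n_samples)
        total += e - s
        covered += int(handled[s:e].sum())
    return covered / total
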