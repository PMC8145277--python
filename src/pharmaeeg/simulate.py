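"""Synthetic paired-session EEG cohorts and behavioral data.

The generators emulate the statistical structure a within-subject
pharmaco-EEG study assumes: a 29-channel cap sampled natively at 2500 Hz,
an occipitally dominant alpha rhythm riding on 1/f background noise plus
weaker canonical band components, stereotyped artifacts (blinks, muscle
bursts, step transients, flat segments), paired baseline/follow-up sessions
with configurable condition effects expressed *generatively* (component
amplitude scaling, never by editing feature values), a Simon task with
exact 60/40 per-block congruency counts and shifted-lognormal reaction
times, and binomial-type recall counts for two memory tasks.

Every generator is a pure function of its config and seed.  Seeds for
subject/condition/session streams are derived as
``SeedSequence((master_seed, subject, condition_index, session_index))``
so that adding subjects or conditions never perturbs earlier streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import RawRecording
from .montage import MontageSpec, frontal_weights, generate_montage, posterior_weights

#: EEG conditions of the paired study design, in recording order.
EEG_CONDITIONS = ("rest1", "rest2", "wp_learning", "wp_recall", "vr_learning", "simon")

SESSIONS = ("baseline", "followup")

#: Canonical band components of the simulator (Hz edges, default RMS in uV).
BAND_COMPONENTS: dict[str, tuple[float, float, float]] = {
    "delta": (1.0, 3.0, 3.0),
    "theta": (3.0, 7.0, 2.5),
    "beta": (13.0, 30.0, 2.5),
    "gamma": (30.0, 45.0, 1.2),
}

FEATURE_NAMES = (
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
    "brain_rate", "entropy", "power",
)

ARTIFACT_KINDS = ("blink", "muscle", "step", "flatline")


@dataclass(frozen=True)
class EEGSimConfig:
    """Parameters of the continuous-EEG generator.

    ``band_effects`` maps a condition name to per-component amplitude
    multipliers applied on an electrode group, e.g.
    ``{"simon": [("beta", ("Fz", "Cz"), 1.3)]}``.
    """

    duration: float = 300.0
    fs_native: float = 2500.0
    alpha_peak_hz: float = 10.0
    alpha_amp_uv: float = 20.0
    alpha_coherence: float = 0.4  # fraction of alpha variance from the shared source
    noise_amp_uv: float = 10.0
    pink_slope: float = 1.0
    band_levels: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(BAND_COMPONENTS))
    band_effects: dict[str, list[tuple[str, tuple[str, ...], float]]] = field(
        default_factory=dict)
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {"blink": 2.0, "muscle": 0.5, "step": 0.2, "flatline": 0.1})
    blink_amp_uv: float = 150.0
    muscle_rms_uv: float = 60.0
    step_amp_uv: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.fs_native < 512:
            raise ValueError("native sampling rate must be >= 512 Hz")
        for name, (lo, hi, rms) in self.band_levels.items():
            if not (0 < lo < hi) or rms < 0:
                raise ValueError(f"invalid band component {name}")
        for cond, effs in self.band_effects.items():
            for comp, group, mult in effs:
                if mult <= 0:
                    raise ValueError("band-effect multipliers must be > 0")
        for kind, rate in self.artifact_rates.items():
            if rate < 0:
                raise ValueError("artifact rates must be >= 0")


@dataclass(frozen=True)
class EffectSpec:
    """A condition effect on one feature family over an electrode group.

    ``magnitude`` is the relative amplitude change of the generative
    component(s) that drive the feature (see the mapping in
    :func:`effect_component_gains`); ``direction`` is +1 or -1.
    """

    feature_name: str
    electrode_group: tuple[str, ...]
    direction: int
    magnitude: float
    frequency_band: tuple[float, float] | None = None
    condition: str | None = None  # None: applies to every EEG condition

    def __post_init__(self) -> None:
        if self.feature_name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.feature_name!r}")
        if not self.electrode_group:
            raise ValueError("electrode group must be non-empty")
        montage = generate_montage()
        if not set(self.electrode_group) <= set(montage.labels):
            raise ValueError("electrode group must be a subset of montage labels")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.feature_name == "power" and self.frequency_band is None:
            raise ValueError("power effects require a frequency band")


@dataclass(frozen=True)
class InjectedArtifact:
    """Ground-truth record of one injected artifact event."""

    kind: str
    start: int
    end: int
    channels: frozenset[str]


def _derive_seed(*keys: int) -> int:
    """Stable integer seed (< 2^31) from a tuple of integer keys."""
    ss = np.random.SeedSequence(tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _colored_noise(rng: np.random.Generator, n: int, fs: float,
                   slope: float, rms: float) -> np.ndarray:
    """1/f^slope Gaussian noise, scaled to the requested RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-slope / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float, rms: float) -> np.ndarray:
    """Band-limited Gaussian noise on [lo, hi) Hz, scaled to RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        return np.zeros(n)
    x = np.fft.irfft(spec * mask, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _alpha_source(rng: np.random.Generator, n: int, fs: float, peak_hz: float) -> np.ndarray:
    """Amplitude-modulated alpha oscillation with unit RMS."""
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * peak_hz * t + phase)
    # waxing/waning envelope: smoothed positive noise, ~0.4 Hz fluctuations
    env = 1.0 + 0.4 * _band_noise(rng, n, fs, 0.05, 0.8, 1.0)
    env = np.clip(env, 0.2, None)
    x = carrier * env
    return x / x.std()


def effect_component_gains(
    effects: list[EffectSpec],
    labels: tuple[str, ...],
    condition: str,
    band_names: tuple[str, ...],
) -> dict[str, np.ndarray]:
    """Translate feature-level effects into per-channel component gains.

    Mapping (amplitude gains; power scales with the square):

    - ``hjorth_activity``: all components scaled by ``sqrt(1 + d*m)`` so the
      variance changes by the stated fraction.
    - ``power``: the band components overlapping ``frequency_band`` scaled
      by ``sqrt(1 + d*m)``.
    - ``brain_rate`` / ``hjorth_mobility``: spectral tilt — high bands
      (beta/gamma) scaled by ``1 + d*m``, slow bands (delta/theta) and the
      alpha rhythm by ``1 - d*m/2`` (mean frequency moves with ``d``).
    - ``entropy``: direction -1 adds slow burst modulation of depth ``m``
      to the target channels (a heavier-tailed amplitude distribution
      widens the per-epoch bin range and concentrates mass centrally,
      lowering binned entropy); direction +1 scales the alpha component by
      ``1 + m`` (a rhythm-dominated epoch spreads its amplitudes across
      the bin range and carries higher binned entropy than Gaussian
      noise).
    - ``hjorth_complexity``: broadband noise vs alpha ratio scaled by
      ``1 + d*m`` (a purer rhythm has complexity nearer 1).
    """
    components = ("noise", "alpha") + tuple(band_names)
    gains = {c: np.ones(len(labels)) for c in components}
    gains["burst_mod"] = np.zeros(len(labels))
    idx = {l: i for i, l in enumerate(labels)}
    high = [b for b in band_names if b in ("beta", "gamma")]
    low = [b for b in band_names if b in ("delta", "theta")]
    for eff in effects:
        if eff.condition is not None and eff.condition != condition:
            continue
        sel = np.array([idx[l] for l in eff.electrode_group if l in idx], dtype=int)
        if sel.size == 0:
            continue
        d, m = eff.direction, eff.magnitude
        if eff.feature_name == "hjorth_activity":
            g = np.sqrt(max(1.0 + d * m, 1e-6))
            for c in components:
                gains[c][sel] *= g
        elif eff.feature_name == "power":
            lo, hi = eff.frequency_band
            g = np.sqrt(max(1.0 + d * m, 1e-6))
            for b in band_names:
                b_lo, b_hi, _ = BAND_COMPONENTS.get(b, (0, 0, 0))
                if b_lo < hi and b_hi > lo:
                    gains[b][sel] *= g
            if lo <= 10.0 < hi:
                gains["alpha"][sel] *= g
        elif eff.feature_name in ("brain_rate", "hjorth_mobility"):
            for b in high:
                gains[b][sel] *= max(1.0 + d * m, 1e-6)
            for b in low:
                gains[b][sel] *= max(1.0 - d * m / 2.0, 1e-6)
            gains["alpha"][sel] *= max(1.0 - d * m / 2.0, 1e-6)
        elif eff.feature_name == "entropy":
            if d < 0:
                gains["burst_mod"][sel] += m
            else:
                gains["alpha"][sel] *= 1.0 + m
        elif eff.feature_name == "hjorth_complexity":
            gains["noise"][sel] *= max(1.0 + d * m, 1e-6)
            gains["alpha"][sel] *= max(1.0 - d * m / 2.0, 1e-6)
    return gains


def generate_recording(
    montage: MontageSpec,
    config: EEGSimConfig,
    component_gains: dict[str, np.ndarray] | None = None,
) -> RawRecording:
    """Generate a continuous multichannel EEG recording in microvolts.

    The signal is the sum of per-channel 1/f noise, a posteriorly weighted
    coherent alpha rhythm, and independent band-limited components; optional
    ``component_gains`` (per scalp channel) scale individual components.
    Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs_native))
    labels = montage.labels + (montage.eog_label,)
    n_scalp = len(montage.labels)
    data = np.zeros((len(labels), n))

    gains = {c: np.ones(n_scalp) for c in ("noise", "alpha", *config.band_levels)}
    gains["burst_mod"] = np.zeros(n_scalp)
    if component_gains:
        for c, g in component_gains.items():
            gains[c] = np.asarray(g, dtype=float)

    alpha_shared = _alpha_source(rng, n, config.fs_native, config.alpha_peak_hz)
    post_w = posterior_weights(montage)
    coh = np.sqrt(np.clip(config.alpha_coherence, 0.0, 1.0))
    ind = np.sqrt(1.0 - np.clip(config.alpha_coherence, 0.0, 1.0))
    for i in range(n_scalp):
        x = _colored_noise(rng, n, config.fs_native, config.pink_slope,
                           config.noise_amp_uv) * gains["noise"][i]
        # alpha is only partly coherent across the scalp; the independent
        # part survives common-average referencing
        alpha_i = coh * alpha_shared + ind * _alpha_source(
            rng, n, config.fs_native, config.alpha_peak_hz)
        x += alpha_i * (config.alpha_amp_uv / np.sqrt(2.0)) * post_w[i] * gains["alpha"][i]
        for bname, (lo, hi, rms) in config.band_levels.items():
            if rms > 0:
                x += _band_noise(rng, n, config.fs_native, lo, hi, rms) * gains[bname][i]
        depth = gains["burst_mod"][i]
        if depth > 0:
            # slow multiplicative bursting: heavier-tailed amplitudes
            env = 1.0 + depth * _band_noise(rng, n, config.fs_native, 0.5, 4.0, 1.0)
            x = x * np.clip(env, 0.1, None)
        data[i] = x
    # EOG: low-amplitude noise baseline; blinks are added by inject_artifacts
    data[n_scalp] = _colored_noise(rng, n, config.fs_native, 1.0, 5.0)
    return RawRecording(data=data, fs=config.fs_native, labels=labels, montage=montage)


# ---------------------------------------------------------------------------
# artifact injection

_BLINK_DUR_S = 0.4
_MUSCLE_DUR_S = 0.5
_STEP_DUR_S = 0.2  # short DC pop: every 200-ms window overlaps an edge
_FLAT_DUR_S = 2.0


def blink_template(n: int) -> np.ndarray:
    """Raised-cosine transient of unit peak amplitude."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))


def inject_artifacts(
    rec: RawRecording, config: EEGSimConfig
) -> tuple[RawRecording, list[InjectedArtifact]]:
    """Add stereotyped artifacts and return the ground-truth event list.

    Event counts are ``round(rate * duration / 60)`` per kind; onsets are
    drawn uniformly without overlap between events of any kind.  Rates whose
    total event time exceeds the recording duration are rejected.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, 0xA27))
    fs = rec.fs
    durations = {"blink": _BLINK_DUR_S, "muscle": _MUSCLE_DUR_S,
                 "step": _STEP_DUR_S, "flatline": _FLAT_DUR_S}
    counts = {k: int(round(config.artifact_rates.get(k, 0.0) * rec.duration / 60.0))
              for k in ARTIFACT_KINDS}
    total_time = sum(counts[k] * durations[k] for k in counts)
    if total_time > rec.duration:
        raise ValueError("artifact rates produce events exceeding the recording duration")

    data = rec.data.copy()
    montage = rec.montage
    scalp = montage.labels
    n_scalp = len(scalp)
    occupied: list[tuple[int, int]] = []
    truth: list[InjectedArtifact] = []

    def _place(n_len: int) -> int:
        for _ in range(2000):
            start = int(rng.integers(0, rec.n_samples - n_len))
            if all(start + n_len <= s or start >= e for s, e in occupied):
                occupied.append((start, start + n_len))
                return start
        raise ValueError("could not place artifact without overlap; lower the rates")

    frontal = frontal_weights(montage)
    for kind in ARTIFACT_KINDS:
        n_len = int(round(durations[kind] * fs))
        for _ in range(counts[kind]):
            start = _place(n_len)
            end = start + n_len
            if kind == "blink":
                tpl = blink_template(n_len) * config.blink_amp_uv
                for i in range(n_scalp):
                    data[i, start:end] += tpl * frontal[i] * 0.6
                data[n_scalp, start:end] += tpl  # EOG carries the full blink
                chans = frozenset(np.array(scalp)[frontal > 0.3]) | {montage.eog_label}
            elif kind == "muscle":
                k = int(rng.integers(4, 9))
                sel = rng.choice(n_scalp, size=k, replace=False)
                from scipy.signal.windows import tukey

                taper = tukey(n_len, alpha=0.3)  # flat top: burst stays
                # suprathreshold over nearly its whole extent
                for i in sel:
                    burst = _band_noise(rng, n_len, fs, 20.0, min(fs / 2 * 0.9, 100.0),
                                        config.muscle_rms_uv)
                    data[i, start:end] += burst * taper
                chans = frozenset(scalp[i] for i in sel)
            elif kind == "step":
                k = int(rng.integers(1, 4))
                sel = rng.choice(n_scalp, size=k, replace=False)
                sign = rng.choice([-1.0, 1.0])
                for i in sel:
                    data[i, start:end] += sign * config.step_amp_uv
                chans = frozenset(scalp[i] for i in sel)
            else:  # flatline
                k = int(rng.integers(1, 4))
                sel = rng.choice(n_scalp, size=k, replace=False)
                for i in sel:
                    data[i, start:end] = data[i, start]
                chans = frozenset(scalp[i] for i in sel)
            truth.append(InjectedArtifact(kind=kind, start=start, end=end, channels=chans))

    truth.sort(key=lambda a: a.start)
    out = rec.copy_with(data=data)
    return out, truth


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class SubjectRecordings:
    """All recordings of one subject: condition -> {session -> RawRecording}."""

    subject: int
    recordings: dict[str, dict[str, RawRecording]]
    truth: dict[str, dict[str, list[InjectedArtifact]]]


def generate_subject_cohort(
    n_subjects: int,
    effects: list[EffectSpec],
    config: EEGSimConfig,
    conditions: tuple[str, ...] = EEG_CONDITIONS,
    inject: bool = True,
) -> list[SubjectRecordings]:
    """Paired baseline/follow-up recordings for every subject and condition.

    Follow-up recordings carry the injected ``effects`` (translated into
    generative component gains); subject-level amplitude/peak-frequency
    variation is shared across that subject's sessions so paired contrasts
    see within-subject correlation, with smaller independent session-level
    jitter providing the difference noise.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not conditions:
        raise ValueError("condition list must be non-empty")
    montage = generate_montage()
    band_names = tuple(config.band_levels)
    cohort: list[SubjectRecordings] = []
    for s in range(n_subjects):
        subj_rng = np.random.default_rng(_derive_seed(config.seed, s, 0x5AB))
        alpha_mult = float(np.exp(subj_rng.normal(0.0, 0.20)))
        noise_mult = float(np.exp(subj_rng.normal(0.0, 0.15)))
        peak_jit = float(subj_rng.normal(0.0, 0.4))
        recs: dict[str, dict[str, RawRecording]] = {}
        truths: dict[str, dict[str, list[InjectedArtifact]]] = {}
        for ci, cond in enumerate(conditions):
            recs[cond] = {}
            truths[cond] = {}
            for sess_i, session in enumerate(SESSIONS):
                sess_rng = np.random.default_rng(_derive_seed(config.seed, s, ci, sess_i))
                sess_alpha = alpha_mult * float(np.exp(sess_rng.normal(0.0, 0.05)))
                sess_noise = noise_mult * float(np.exp(sess_rng.normal(0.0, 0.04)))
                cfg = replace(
                    config,
                    alpha_amp_uv=config.alpha_amp_uv * sess_alpha,
                    noise_amp_uv=config.noise_amp_uv * sess_noise,
                    alpha_peak_hz=config.alpha_peak_hz + peak_jit,
                    seed=_derive_seed(config.seed, s, ci, sess_i, 0xEE6),
                )
                gains = None
                if session == "followup" and effects:
                    gains = effect_component_gains(effects, montage.labels, cond, band_names)
                for comp, group, mult in config.band_effects.get(cond, []):
                    if gains is None:
                        gains = {c: np.ones(len(montage.labels))
                                 for c in ("noise", "alpha", *band_names)}
                    sel = [montage.labels.index(l) for l in group]
                    gains[comp][sel] *= mult
                rec = generate_recording(montage, cfg, component_gains=gains)
                if inject:
                    rec, truth = inject_artifacts(rec, cfg)
                else:
                    truth = []
                recs[cond][session] = rec
                truths[cond][session] = truth
        cohort.append(SubjectRecordings(subject=s, recordings=recs, truth=truths))
    return cohort


# ---------------------------------------------------------------------------
# behavioral generators

@dataclass(frozen=True)
class SimonConfig:
    """Simon-task session generator parameters.

    Reaction times follow a shifted lognormal: ``rt = shift + effect*IC +
    exp(mu + sigma*Z)`` with ``exp(mu)`` set so the congruent median equals
    ``median_rt_ms``; the congruency effect is additive on the shift, so the
    population median difference equals ``congruency_effect_ms`` exactly.
    """

    n_trials: int = 400
    block_size: int = 100
    p_congruent: float = 0.6
    congruency_effect_ms: float = 48.0
    median_rt_ms: float = 462.0
    rt_shift_ms: float = 200.0
    rt_sigma: float = 0.30
    p_correct_congruent: float = 0.99
    p_correct_incongruent: float = 0.96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials % self.block_size != 0:
            raise ValueError("n_trials must be divisible by block_size")
        if not 0 < self.p_congruent < 1:
            raise ValueError("p_congruent must be in (0, 1)")
        n_c = self.block_size * self.p_congruent
        if abs(n_c - round(n_c)) > 1e-9:
            raise ValueError("p_congruent must give an integer count per block")
        if self.median_rt_ms <= self.rt_shift_ms:
            raise ValueError("median RT must exceed the lognormal shift")


def generate_simon_session(config: SimonConfig) -> pd.DataFrame:
    """One Simon-task session as a tidy trial table.

    Columns: ``task, trial_index, block, condition, rt_ms, correct``.
    Every block contains exactly ``block_size * p_congruent`` congruent
    trials in randomised order.
    """
    rng = np.random.default_rng(config.seed)
    n_blocks = config.n_trials // config.block_size
    n_c = int(round(config.block_size * config.p_congruent))
    rows = []
    mu = np.log(config.median_rt_ms - config.rt_shift_ms)
    for b in range(n_blocks):
        conds = np.array(["congruent"] * n_c
                         + ["incongruent"] * (config.block_size - n_c))
        rng.shuffle(conds)
        for cond in conds:
            ic = cond == "incongruent"
            rt = (config.rt_shift_ms
                  + (config.congruency_effect_ms if ic else 0.0)
                  + np.exp(mu + config.rt_sigma * rng.standard_normal()))
            p_ok = config.p_correct_incongruent if ic else config.p_correct_congruent
            rows.append({
                "task": "simon",
                "trial_index": len(rows),
                "block": b,
                "condition": cond,
                "rt_ms": float(rt),
                "correct": bool(rng.random() < p_ok),
            })
    return pd.DataFrame(rows)


def generate_recall_counts(
    task: str,
    n_subjects: int,
    item_total: int,
    effect: float = 0.0,
    seed: int = 0,
    mean_p: float = 0.36,
    subject_sd: float = 0.7,
    session_sd: float = 0.25,
) -> pd.DataFrame:
    """Paired recall counts for a memory task (binomial-type noise).

    Per-subject recall ability lives on the logit scale: subject effects
    are shared across sessions (pairing), session effects are independent,
    and ``effect`` shifts the follow-up logit.  Counts are
    ``Binomial(item_total, p)`` and therefore bounded by ``item_total``.
    Columns: ``task, subject, session, recall_count, item_total``.
    """
    if item_total <= 0:
        raise ValueError("item_total must be positive")
    rng = np.random.default_rng(seed)
    base_logit = np.log(mean_p / (1.0 - mean_p))
    rows = []
    for s in range(n_subjects):
        subj = base_logit + subject_sd * rng.standard_normal()
        for session in SESSIONS:
            logit = subj + session_sd * rng.standard_normal()
            if session == "followup":
                logit += effect
            p = 1.0 / (1.0 + np.exp(-logit))
            count = int(rng.binomial(item_total, p))
            rows.append({"task": task, "subject": s, "session": session,
                         "recall_count": count, "item_total": item_total})
    return pd.DataFrame(rows)


def generate_score_table(
    measure: str,
    n_subjects: int,
    location: float,
    scale: float,
    effect: float = 0.0,
    seed: int = 0,
    integer: bool = True,
) -> pd.DataFrame:
    """Paired neuropsychological-style scores (integer scales, no effect by
    default) fed to the same Wilcoxon/BH machinery as real score tables."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        subj = location + scale * rng.standard_normal()
        for session in SESSIONS:
            val = subj + 0.5 * scale * rng.standard_normal()
            if session == "followup":
                val += effect
            rows.append({"measure": measure, "subject": s, "session": session,
                         "score": int(round(val)) if integer else float(val)})
    return pd.DataFrame(rows)
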