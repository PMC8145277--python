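"""Preprocessing: from continuous EEG to clean 1-s common-average epochs.

The stage order is fixed and mirrors a conventional pharmaco-EEG chain:

1. zero-phase Butterworth band-pass 0.5-100 Hz (4th order, applied
   forward-backward: 48 dB/oct combined asymptotic roll-off) plus a
   zero-phase 50 Hz notch (Q = 35);
2. polyphase downsampling to 256 Hz;
3. deterministic ocular correction by least-squares regression of the EOG
   channel out of every scalp channel (replacing interactive ICA review);
4. automatic artifact detection with three per-channel criteria evaluated
   on sliding windows at 1-sample stride: maximum gradient 50 uV/ms,
   maximum peak-to-peak difference 200 uV within 200 ms, minimum
   peak-to-peak difference 0.5 uV within 100 ms (flatline);
5. whole-recording repair of bad channels by unweighted neighbour
   averaging; interval-wise repair of artifacts confined to fewer than
   three channels; exclusion of all remaining artifact intervals;
6. removal of TP9/TP10, tiling of each remaining contiguous segment with
   non-overlapping 1-s epochs (remainder discarded), and common-average
   re-referencing across the 27 retained channels within each epoch.

Thresholds are expressed in physical units so the chain is rate-agnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import ArtifactAnnotation, EpochSet, RawRecording
from .montage import EXCLUDED_LABELS, neighbor_adjacency

logger = logging.getLogger(__name__)

TARGET_FS = 256.0

GRADIENT_UV_PER_MS = 50.0
AMPLITUDE_UV = 200.0
AMPLITUDE_WINDOW_S = 0.2
FLATLINE_UV = 0.5
FLATLINE_WINDOW_S = 0.1
GUARD_MARGIN_S = 0.1
FLATLINE_MARGIN_S = 0.65  # absorbs the band-pass settling zone around flat segments


class PreprocessingError(ValueError):
    """Configuration or data problem that invalidates a preprocessing step."""


def bandpass_and_notch(rec: RawRecording, l_freq: float = 0.5, h_freq: float = 100.0,
                       notch_hz: float = 50.0, notch_q: float = 35.0) -> RawRecording:
    """Zero-phase band-pass plus line-noise notch.

    4th-order Butterworth applied with ``sosfiltfilt`` (zero phase, squared
    magnitude response -> 48 dB/oct combined roll-off); second-order IIR
    notch applied with ``filtfilt``.
    """
    nyq = rec.fs / 2.0
    if h_freq >= nyq:
        raise PreprocessingError(
            f"band edge {h_freq} Hz requires fs > {2 * h_freq} Hz (fs = {rec.fs})")
    sos = signal.butter(4, [l_freq, h_freq], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch_hz < nyq:
        b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    return rec.copy_with(data=data)


def resample_to_256(rec: RawRecording, target_fs: float = TARGET_FS) -> RawRecording:
    """Polyphase (anti-aliased) resampling to 256 Hz.

    The rate ratio must be (close to) rational; annotation sample indices
    are rescaled conservatively (floor start, ceil end).
    """
    if rec.fs == target_fs:
        return rec
    if rec.fs < target_fs:
        raise PreprocessingError("upsampling not supported; record at >= 256 Hz")
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    if abs(float(ratio) * rec.fs - target_fs) > 1e-6:
        raise PreprocessingError(
            f"sampling-rate ratio {target_fs}/{rec.fs} is not rational enough")
    up, down = ratio.numerator, ratio.denominator
    data = signal.resample_poly(rec.data, up, down, axis=1)
    scale = float(ratio)
    anns = [ArtifactAnnotation(
        start=int(np.floor(a.start * scale)),
        end=min(int(np.ceil(a.end * scale)), data.shape[1]),
        channels=a.channels, reason=a.reason) for a in rec.annotations]
    return RawRecording(data=data, fs=target_fs, labels=rec.labels,
                        montage=rec.montage, annotations=anns)


def ocular_correction(rec: RawRecording, eog_channel: str | None = None) -> RawRecording:
    """Regress the EOG channel out of every scalp channel.

    For each scalp channel x: ``x <- x - (cov(x, eog)/var(eog)) * eog``
    computed on demeaned signals.  A zero (or constant) EOG channel leaves
    the recording unchanged.
    """
    eog_channel = eog_channel or rec.montage.eog_label
    if eog_channel not in rec.labels:
        raise PreprocessingError(f"EOG channel {eog_channel!r} not in recording")
    eog_idx = rec.labels.index(eog_channel)
    eog = rec.data[eog_idx] - rec.data[eog_idx].mean()
    var = float(eog @ eog)
    data = rec.data.copy()
    if var > 0:
        for i, lab in enumerate(rec.labels):
            if lab == eog_channel:
                continue
            x = data[i]
            beta = float((x - x.mean()) @ eog) / var
            data[i] = x - beta * eog
    return rec.copy_with(data=data)


def _window_ptp(x: np.ndarray, w: int) -> np.ndarray:
    """Peak-to-peak over every length-``w`` window starting at 0..n-w."""
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(x, w)
    return win.max(axis=-1) - win.min(axis=-1)


def _windows_to_mask(viol: np.ndarray, w: int, n: int) -> np.ndarray:
    """Mark every sample covered by a violating window (start-indexed)."""
    delta = np.zeros(n + 1, dtype=int)
    starts = np.flatnonzero(viol)
    np.add.at(delta, starts, 1)
    np.add.at(delta, np.minimum(starts + w, n), -1)
    return np.cumsum(delta[:-1]) > 0


def _mask_to_intervals(mask: np.ndarray, margin: int, n: int) -> list[tuple[int, int]]:
    """Maximal flagged intervals, grown by ``margin`` samples and re-merged."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        s, e = max(0, s - margin), min(n, e + margin)
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def detect_artifacts(rec: RawRecording,
                     gradient_uv_per_ms: float = GRADIENT_UV_PER_MS,
                     amplitude_uv: float = AMPLITUDE_UV,
                     flatline_uv: float = FLATLINE_UV,
                     guard_margin_s: float = GUARD_MARGIN_S,
                     flatline_margin_s: float = FLATLINE_MARGIN_S,
                     scalp_only: bool = True) -> list[ArtifactAnnotation]:
    """Apply the three automatic artifact criteria per channel.

    Flags samples where the one-sample gradient exceeds 50 uV/ms, where the
    peak-to-peak range of any 200-ms window exceeds 200 uV, or where the
    peak-to-peak range of any 100-ms window stays below 0.5 uV; flagged
    samples are merged into maximal intervals grown by the guard margin.
    Flatline intervals use a wider margin (default 0.65 s): after zero-phase
    filtering, the edges of a truly flat segment carry the filter's
    settling transient and exceed the 0.5 uV bound without being clean.
    """
    fs = rec.fs
    n = rec.n_samples
    w_amp = int(round(AMPLITUDE_WINDOW_S * fs))
    w_flat = int(round(FLATLINE_WINDOW_S * fs))
    margin = int(round(guard_margin_s * fs))
    eog = rec.montage.eog_label
    out: list[ArtifactAnnotation] = []
    for i, lab in enumerate(rec.labels):
        if scalp_only and lab == eog:
            continue
        x = rec.data[i]
        grad = np.abs(np.diff(x)) * fs / 1000.0
        masks = {
            "gradient": _windows_to_mask(grad > gradient_uv_per_ms, 2, n),
            "amplitude": _windows_to_mask(_window_ptp(x, w_amp) > amplitude_uv, w_amp, n)
            if n >= w_amp else np.zeros(n, bool),
            "flatline": _windows_to_mask(_window_ptp(x, w_flat) < flatline_uv, w_flat, n)
            if n >= w_flat else np.zeros(n, bool),
        }
        flat_margin = max(margin, int(round(flatline_margin_s * fs)))
        for reason, mask in masks.items():
            use_margin = flat_margin if reason == "flatline" else margin
            for s, e in _mask_to_intervals(mask, use_margin, n):
                out.append(ArtifactAnnotation(start=s, end=e,
                                              channels=frozenset({lab}), reason=reason))
    out.sort(key=lambda a: (a.start, a.end, sorted(a.channels)))
    return out


def repair_bad_channels(rec: RawRecording, bad_labels: list[str],
                        montage=None) -> RawRecording:
    """Replace each bad channel by the unweighted mean of its clean neighbours.

    Neighbourhoods come from the Delaunay triangulation of the template
    layout.  All repairs draw from the original (pre-repair) data, which
    makes the operation idempotent.  A bad channel without any clean
    neighbour raises :class:`PreprocessingError`.
    """
    if not bad_labels:
        return rec
    montage = montage or rec.montage
    scalp = tuple(l for l in rec.labels if l in montage.labels)
    adj = neighbor_adjacency(scalp)
    bad = set(bad_labels)
    if not bad <= set(scalp):
        raise PreprocessingError("bad labels must be scalp channels of the recording")
    data = rec.data.copy()
    src = rec.data
    for lab in sorted(bad):
        clean = [nb for nb in adj[lab] if nb not in bad]
        if not clean:
            raise PreprocessingError(f"channel {lab} has no clean neighbour to repair from")
        idxs = [rec.labels.index(nb) for nb in clean]
        data[rec.labels.index(lab)] = src[idxs].mean(axis=0)
    return rec.copy_with(data=data)


def interpolate_or_exclude(
    rec: RawRecording,
    annotations: list[ArtifactAnnotation],
    max_repair_channels: int = 2,
) -> tuple[RawRecording, list[tuple[int, int]]]:
    """Repair few-channel artifact intervals in place; return the rest.

    Annotated intervals whose channel set involves fewer than three scalp
    channels are repaired sample-wise by averaging clean neighbours within
    the interval; all other intervals (and unrepairable ones) are returned
    as exclusion intervals ``[start, end)``.
    """
    montage = rec.montage
    scalp = tuple(l for l in rec.labels if l in montage.labels)
    adj = neighbor_adjacency(scalp)
    data = rec.data.copy()
    exclusions: list[tuple[int, int]] = []
    # cluster overlapping annotations into events so channels flagged at the
    # same time count together (per-channel intervals rarely align exactly)
    events: list[tuple[int, int, set[str]]] = []
    for ann in sorted(annotations, key=lambda a: (a.start, a.end)):
        chans = set(ann.channels) & set(scalp)
        if events and ann.start < events[-1][1]:
            s0, e0, c0 = events[-1]
            events[-1] = (s0, max(e0, ann.end), c0 | chans)
        else:
            events.append((ann.start, ann.end, chans))
    for s, e, chans in events:
        if not chans:
            continue
        if len(chans) <= max_repair_channels:
            ok = True
            for lab in sorted(chans):
                clean = [nb for nb in adj[lab] if nb not in chans]
                if not clean:
                    ok = False
                    break
                idxs = [rec.labels.index(nb) for nb in clean]
                data[rec.labels.index(lab), s:e] = rec.data[idxs, s:e].mean(axis=0)
            if ok:
                continue
        exclusions.append((s, e))
    exclusions.sort()
    return rec.copy_with(data=data), exclusions


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def exclude_reference_and_segment(
    rec: RawRecording,
    exclusions: list[tuple[int, int]],
    condition: str = "",
) -> EpochSet:
    """Drop TP9/TP10 (and EOG), cut exclusions, tile 1-s epochs, re-reference.

    Each remaining contiguous segment is tiled with non-overlapping 1-s
    (``fs``-sample) epochs anchored at the segment start; remainders shorter
    than 1 s are discarded.  The common average over the 27 retained
    channels is subtracted per sample within each epoch.
    """
    keep = [l for l in rec.labels
            if l in rec.montage.labels and l not in EXCLUDED_LABELS]
    idxs = [rec.labels.index(l) for l in keep]
    data = rec.data[idxs]
    n = data.shape[1]
    fs_i = int(round(rec.fs))

    merged = merge_intervals([(max(0, s), min(n, e)) for s, e in exclusions if e > 0 and s < n])
    segments: list[tuple[int, int]] = []
    cursor = 0
    for s, e in merged:
        if s > cursor:
            segments.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < n:
        segments.append((cursor, n))

    epochs = []
    for s, e in segments:
        for k in range((e - s) // fs_i):
            epochs.append(data[:, s + k * fs_i: s + (k + 1) * fs_i])
    if not epochs:
        warnings.warn(f"no full 1-s epoch left after exclusion ({condition or 'recording'})")
        arr = np.empty((0, len(keep), fs_i))
    else:
        arr = np.stack(epochs)
        arr = arr - arr.mean(axis=1, keepdims=True)  # common average per sample
    logger.info("segmented %s: %d exclusion(s), %d epoch(s)",
                condition or "recording", len(merged), arr.shape[0])
    return EpochSet(condition=condition, epochs=arr, fs=rec.fs, labels=tuple(keep))


def preprocess_recording(rec: RawRecording, condition: str = "",
                         bad_labels: list[str] | None = None) -> EpochSet:
    """Run the full fixed-order preprocessing chain on one recording."""
    logger.info("preprocess %s: %.1f s at %g Hz", condition or "recording",
                rec.duration, rec.fs)
    rec = bandpass_and_notch(rec)
    rec = resample_to_256(rec)
    rec = ocular_correction(rec)
    annotations = detect_artifacts(rec)
    logger.info("detected %d artifact annotation(s)", len(annotations))
    if bad_labels:
        rec = repair_bad_channels(rec, bad_labels)
    rec, exclusions = interpolate_or_exclude(rec, annotations)
    return exclude_reference_and_segment(rec, exclusions, condition=condition)
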