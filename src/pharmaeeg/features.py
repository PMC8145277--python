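"""Quantitative EEG features computed on 1-s epochs.

Four feature families, all evaluated per epoch and per electrode and then
averaged over the epochs of a condition:

* **Hjorth parameters** — activity ``A = var(x)`` (uV^2), mobility
  ``M = sqrt(var(x')/var(x))`` (a mean-frequency proxy; for a pure sine at
  angular frequency w, M -> w), and complexity ``C = M(x')/M(x)`` (a
  bandwidth proxy; exactly 1 for a pure sine).  The derivative is realised
  as the first difference scaled by the sampling rate, so M carries
  rad/s-equivalent units; only ratios matter for M and C.
* **Brain-rate** — the spectrum-weighted mean frequency
  ``fb = sum_i f_i * p_i / sum_i p_i`` over five canonical bands with
  centre frequencies f = (2, 4, 6, 10, 18) Hz, where ``p_i`` is the mean
  power inside band i; an arousal index bounded by [2, 18] Hz.
* **Shannon entropy** — ``H = -sum p(x_i) log2 p(x_i)`` of the amplitude
  histogram of the epoch, using a fixed number of equal-width bins
  (default 15, a cohort-level Freedman-Diaconis grand average) spanning the
  epoch's [min, max]; 0 <= H <= log2(n_bins) bits.
* **Normalised power spectrum** — Hann-tapered FFT of the demeaned epoch at
  1 Hz resolution, restricted to the analysis band and divided by the mean
  power over that band (band mean exactly 1 after normalisation).

The analysis band defaults to 1-40 Hz inclusive (exactly 40 one-hertz
bins); a wider 0.5-45 Hz option is available via ``band``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet

DEFAULT_ENTROPY_BINS = 15
DEFAULT_BAND = (1.0, 40.0)
WIDE_BAND = (0.5, 45.0)

UNIVARIATE_FEATURES = (
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity", "brain_rate", "entropy",
)


class DegenerateSignalError(ValueError):
    """Raised when a feature is undefined on a (near-)constant epoch."""


@dataclass(frozen=True)
class BrainRateBands:
    """The five canonical bands of the brain-rate statistic.

    The centre set f = (2, 4, 6, 10, 18) Hz is fixed; the edges are a
    package decision (the statistic's definition fixes only the centres):
    delta [0.5, 3), theta [3, 5), low-alpha [5, 7.5), alpha/low-beta
    [7.5, 13), beta [13, 30).
    """

    centers: tuple[float, ...] = (2.0, 4.0, 6.0, 10.0, 18.0)
    edges: tuple[tuple[float, float], ...] = (
        (0.5, 3.0), (3.0, 5.0), (5.0, 7.5), (7.5, 13.0), (13.0, 30.0))

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.edges):
            raise ValueError("need one edge pair per centre")
        for i, (lo, hi) in enumerate(self.edges):
            if not lo < hi:
                raise ValueError("band edges must be increasing")
            if i and abs(lo - self.edges[i - 1][1]) > 1e-9:
                raise ValueError("bands must be contiguous and ordered")


@dataclass
class Spectrum:
    """Per-channel power on a 1-Hz frequency grid."""

    freqs: np.ndarray
    power: np.ndarray  # (..., n_freqs)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape[-1] != self.freqs.size:
            raise ValueError("power's last axis must match the frequency grid")
        if (self.power < -1e-12).any():
            raise ValueError("power must be non-negative")


def hjorth_parameters(epoch: np.ndarray, fs: float = 256.0) -> tuple[float, float, float]:
    """Activity (uV^2), mobility and complexity of one epoch.

    Raises :class:`DegenerateSignalError` on a constant epoch (activity is
    then 0 but mobility and complexity are undefined).
    """
    x = np.asarray(epoch, dtype=float)
    activity = float(np.var(x))
    if activity <= 0.0:
        raise DegenerateSignalError(
            "constant epoch: activity is 0 and mobility/complexity are undefined")
    dx = np.diff(x) * fs
    var_dx = float(np.var(dx))
    mobility = float(np.sqrt(var_dx / activity))
    ddx = np.diff(dx) * fs
    var_ddx = float(np.var(ddx))
    if var_dx <= 0.0:
        raise DegenerateSignalError("derivative is constant; complexity undefined")
    mobility_dx = np.sqrt(var_ddx / var_dx)
    complexity = float(mobility_dx / mobility)
    return activity, mobility, complexity


def _hjorth_vectorized(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hjorth triplet along the last axis; degenerate entries become NaN."""
    var0 = x.var(axis=-1)
    dx = np.diff(x, axis=-1) * fs
    var1 = dx.var(axis=-1)
    ddx = np.diff(dx, axis=-1) * fs
    var2 = ddx.var(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mob = np.sqrt(var1 / var0)
        comp = np.sqrt(var2 / var1) / mob
    mob = np.where(var0 > 0, mob, np.nan)
    comp = np.where((var0 > 0) & (var1 > 0), comp, np.nan)
    return var0, mob, comp


def power_spectrum(epoch: np.ndarray, fs: float = 256.0,
                   band: tuple[float, float] = DEFAULT_BAND,
                   normalize: bool = True) -> Spectrum:
    """Hann-tapered FFT power of demeaned epoch(s) at 1-Hz resolution.

    ``epoch`` may be 1-D (samples) or N-D with samples on the last axis.
    The returned grid is the integer frequencies inside ``band`` (inclusive
    edges); with normalisation the mean over the band is exactly 1 per
    channel.
    """
    x = np.asarray(epoch, dtype=float)
    n = x.shape[-1]
    x = x - x.mean(axis=-1, keepdims=True)
    taper = np.hanning(n)
    spec = np.fft.rfft(x * taper, axis=-1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    freqs, power = freqs[mask], power[..., mask]
    if normalize:
        mean = power.mean(axis=-1, keepdims=True)
        if np.any(mean <= 0):
            raise DegenerateSignalError("all-zero epoch: normalisation undefined")
        power = power / mean
    return Spectrum(freqs=freqs, power=power, normalized=normalize)


def brain_rate(spectrum: Spectrum, bands: BrainRateBands | None = None) -> np.ndarray | float:
    """Spectrum-weighted mean frequency fb over the five canonical bands."""
    bands = bands or BrainRateBands()
    if spectrum.freqs[0] > bands.edges[0][0] + 1.0 or spectrum.freqs[-1] < bands.edges[-1][1] - 1.0:
        warnings.warn("spectrum does not fully cover the brain-rate bands")
    p = []
    for lo, hi in bands.edges:
        m = (spectrum.freqs >= lo) & (spectrum.freqs < hi)
        if not m.any():
            raise ValueError(f"no spectral bins inside band [{lo}, {hi})")
        p.append(spectrum.power[..., m].mean(axis=-1))
    p = np.stack(p, axis=-1)
    total = p.sum(axis=-1)
    if np.any(total <= 0):
        raise DegenerateSignalError("all-zero spectrum: brain-rate undefined")
    fb = (p * np.asarray(bands.centers)).sum(axis=-1) / total
    return float(fb) if np.ndim(fb) == 0 else fb


def fd_bin_count(samples: np.ndarray) -> int:
    """Freedman-Diaconis bin count: ``ceil(range / (2*IQR*n^(-1/3)))``.

    Quantiles use linear interpolation (type 7).  A zero IQR falls back to
    a single bin with a warning.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples for the Freedman-Diaconis rule")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    rng = float(x.max() - x.min())
    if iqr <= 0 or rng <= 0:
        warnings.warn("zero IQR or range: falling back to a single bin")
        return 1
    width = 2.0 * iqr * n ** (-1.0 / 3.0)
    return int(np.ceil(rng / width))


def shannon_entropy(epoch: np.ndarray, n_bins: int = DEFAULT_ENTROPY_BINS) -> float:
    """Binned amplitude entropy of one epoch, in bits.

    ``n_bins`` equal-width bins span the epoch's [min, max]; a constant
    epoch has zero entropy.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    x = np.asarray(epoch, dtype=float).ravel()
    if x.max() == x.min():
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _entropy_rows(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Entropy along the last axis of an N-D array."""
    flat = x.reshape(-1, x.shape[-1])
    out = np.empty(flat.shape[0])
    for i, row in enumerate(flat):
        out[i] = shannon_entropy(row, n_bins)
    return out.reshape(x.shape[:-1])


@dataclass(frozen=True)
class FeatureConfig:
    entropy_bins: int = DEFAULT_ENTROPY_BINS
    band: tuple[float, float] = DEFAULT_BAND
    brain_rate_bands: BrainRateBands = field(default_factory=BrainRateBands)


def condition_features(epochs: EpochSet, config: FeatureConfig | None = None) -> pd.DataFrame:
    """Per-epoch features averaged per electrode for one condition.

    Returns a tidy frame with columns ``condition, feature, electrode,
    freq_hz, value``; ``freq_hz`` is NaN for the univariate features and
    the 1-Hz bin centre for power.  Spectra are normalised per epoch before
    averaging.
    """
    config = config or FeatureConfig()
    if epochs.n_epochs == 0:
        raise ValueError("cannot compute features on an empty EpochSet")
    x = epochs.epochs  # (E, C, N)
    fs = epochs.fs
    act, mob, comp = _hjorth_vectorized(x, fs)
    ent = _entropy_rows(x, config.entropy_bins)
    spec = power_spectrum(x, fs=fs, band=config.band)
    fb = brain_rate(spec, config.brain_rate_bands)

    rows = []
    per_epoch = {
        "hjorth_activity": act, "hjorth_mobility": mob,
        "hjorth_complexity": comp, "brain_rate": fb, "entropy": ent,
    }
    for feat, vals in per_epoch.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(vals, axis=0)  # (C,)
        for ci, lab in enumerate(epochs.labels):
            rows.append({"condition": epochs.condition, "feature": feat,
                         "electrode": lab, "freq_hz": np.nan, "value": float(mean[ci])})
    mean_pow = spec.power.mean(axis=0)  # (C, F)
    for fi, f in enumerate(spec.freqs):
        for ci, lab in enumerate(epochs.labels):
            rows.append({"condition": epochs.condition, "feature": "power",
                         "electrode": lab, "freq_hz": float(f),
                         "value": float(mean_pow[ci, fi])})
    return pd.DataFrame(rows)
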