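"""In-memory containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:
    from .montage import MontageSpec

ARTIFACT_REASONS = ("gradient", "amplitude", "flatline", "manual", "injected")


@dataclass(frozen=True)
class ArtifactAnnotation:
    """A half-open sample interval ``[start, end)`` flagged on some channels."""

    start: int
    end: int
    channels: frozenset[str]
    reason: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("annotation interval must satisfy start < end")
        if self.reason not in ARTIFACT_REASONS:
            raise ValueError(f"unknown artifact reason {self.reason!r}")

    def shifted(self, k: int) -> "ArtifactAnnotation":
        return ArtifactAnnotation(self.start + k, self.end + k, self.channels, self.reason)


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is channels x samples; time of sample ``i`` is ``i / fs`` s.
    The channel order of ``data`` matches ``labels``; the EOG channel, when
    present, is included in ``labels`` (it is dropped before epoching).
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    montage: "MontageSpec"
    annotations: list[ArtifactAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be channels x samples matching labels")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        for ann in self.annotations:
            if not ann.channels <= set(self.labels):
                raise ValueError("annotation channels must be recording labels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def copy_with(self, **kw) -> "RawRecording":
        if "data" in kw:
            kw.setdefault("annotations", list(self.annotations))
        return replace(self, **kw)


@dataclass
class EpochSet:
    """Per-condition collection of 1-s common-average-referenced epochs.

    ``epochs`` is epoch x channel x samples with exactly ``fs`` samples per
    epoch (1 s).  Channels are the 27 retained scalp electrodes.
    """

    condition: str
    epochs: np.ndarray
    fs: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be epoch x channel x sample")
        if self.epochs.shape[1] != len(self.labels):
            raise ValueError("channel axis must match labels")
        if self.epochs.shape[0] and self.epochs.shape[2] != int(round(self.fs)):
            raise ValueError("each epoch must span exactly 1 s")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]
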