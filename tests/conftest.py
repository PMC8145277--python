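import numpy as np
import pytest

from pharmaeeg.containers import RawRecording
from pharmaeeg.montage import generate_montage
from pharmaeeg.simulate import EEGSimConfig, generate_recording


@pytest.fixture(scope="session")
def montage():
    return generate_montage()


@pytest.fixture(scope="session")
def short_recording(montage):
    """10 s of default synthetic EEG at 512 Hz (no artifacts)."""
    cfg = EEGSimConfig(duration=10.0, fs_native=512.0, seed=101)
    return generate_recording(montage, cfg)


def make_recording(montage, data: np.ndarray, fs: float = 256.0,
                   with_eog: bool = True) -> RawRecording:
    """Wrap a channels x samples array (29 scalp rows) as a RawRecording."""
    labels = montage.labels
    if with_eog:
        labels = labels + (montage.eog_label,)
        if data.shape[0] == 29:
            data = np.vstack([data, np.zeros((1, data.shape[1]))])
    return RawRecording(data=data, fs=fs, labels=labels, montage=montage)


@pytest.fixture
def sine_epoch():
    """10 Hz unit-amplitude sine, one second at 256 Hz."""
    t = np.arange(256) / 256.0
    return np.sin(2 * np.pi * 10 * t)
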