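"""File interfaces: EDF and BrainVision recordings, CSV tables, JSON sidecars.

Synthetic recordings are written as 16-bit EDF (physical unit uV, 1-s data
records) by a small self-contained writer; recordings are read back through
mne's EDF and BrainVision readers.  Trial tables, recall counts and feature
tables travel as tidy CSV; artifact annotations and cluster results as
JSON; study configuration as a single YAML file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ArtifactAnnotation, RawRecording
from .montage import generate_montage

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numeric fields without losing the magnitude
        if isinstance(value, float):
            for prec in range(6, -1, -1):
                s = f"{value:.{prec}g}"
                if len(s) <= width:
                    break
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF with 1-s data records.

    Requires an integer sampling rate; a trailing partial second is
    zero-padded.  Per-channel physical min/max are taken from the data, so
    quantisation error is bounded by (max-min)/65535.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_ch = len(rec.labels)
    n_records = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((n_ch, n_records * fs))
    data[:, : rec.n_samples] = rec.data

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max[flat] = phys_min[flat] + 1.0

    header = b"".join([
        _edf_field(0, 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_ch), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    per_signal = b"".join([
        b"".join(_edf_field(lab, 16) for lab in rec.labels),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in rec.labels),
        b"".join(_edf_field("uV", 8) for _ in rec.labels),
        b"".join(_edf_field(float(v), 8) for v in phys_min),
        b"".join(_edf_field(float(v), 8) for v in phys_max),
        b"".join(_edf_field(_EDF_DIG_MIN, 8) for _ in rec.labels),
        b"".join(_edf_field(_EDF_DIG_MAX, 8) for _ in rec.labels),
        b"".join(_edf_field("", 80) for _ in rec.labels),
        b"".join(_edf_field(fs, 8) for _ in rec.labels),
        b"".join(_edf_field("", 32) for _ in rec.labels),
    ])

    scale = (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_records):
            sl = slice(r * fs, (r + 1) * fs)
            fh.write(digital[:, sl].tobytes())
    return path


def read_edf(path: str | Path) -> RawRecording:
    """Read an EDF recording (via mne) into a RawRecording in uV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for EEG-typed channels
    return RawRecording(data=data, fs=float(raw.info["sfreq"]),
                        labels=tuple(raw.ch_names), montage=generate_montage())


def read_brainvision(vhdr_path: str | Path) -> RawRecording:
    """Read a BrainVision (.vhdr/.vmrk/.eeg) recording into uV."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6
    return RawRecording(data=data, fs=float(raw.info["sfreq"]),
                        labels=tuple(raw.ch_names), montage=generate_montage())


def annotations_to_json(annotations: list[ArtifactAnnotation], path: str | Path) -> Path:
    path = Path(path)
    payload = [{"start": a.start, "end": a.end,
                "channels": sorted(a.channels), "reason": a.reason}
               for a in annotations]
    path.write_text(json.dumps(payload, indent=1))
    return path


def annotations_from_json(path: str | Path) -> list[ArtifactAnnotation]:
    payload = json.loads(Path(path).read_text())
    return [ArtifactAnnotation(start=d["start"], end=d["end"],
                               channels=frozenset(d["channels"]), reason=d["reason"])
            for d in payload]


def write_feature_table(table: pd.DataFrame, path: str | Path,
                        config: dict | None = None) -> Path:
    """Tidy feature CSV plus a JSON sidecar with the feature configuration."""
    path = Path(path)
    table.to_csv(path, index=False)
    if config is not None:
        Path(str(path) + ".json").write_text(json.dumps(config, indent=1, default=str))
    return path


def clusters_to_json(clusters_by_contrast: dict, path: str | Path) -> Path:
    """Cluster results as JSON: contrast -> list of cluster dicts."""
    payload = {}
    for contrast, results in clusters_by_contrast.items():
        payload[contrast] = [{
            "members": list(r.members), "mass": r.mass, "polarity": r.polarity,
            "p_value": r.p_value, "scheme": r.scheme,
            "n_permutations": r.n_permutations} for r in results]
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return path
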