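"""Electrode montage: the 29-channel 10-20 cap used throughout the pipeline.

The recording montage is a 29 Ag-AgCl electrode cap (10-20 extension),
online-referenced against FCz with one auxiliary EOG electrode below the
right eye.  Template positions are taken from the standard 10-05 layout and
normalised to the unit sphere; they are used for posterior/frontal weighting
in the simulator, for neighbour-based channel repair, and as the spatial
substrate of the cluster permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

#: The 29 scalp electrodes of the cap, in amplifier order.
SCALP_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz",
    "FC1", "FC2", "CP1", "CP2", "FC5", "FC6", "CP5", "CP6", "TP9", "TP10",
)

#: Electrodes excluded from analysis (mastoid-adjacent, muscle-dominated).
EXCLUDED_LABELS: tuple[str, ...] = ("TP9", "TP10")

REFERENCE_LABEL = "FCz"
EOG_LABEL = "EOG"


@dataclass(frozen=True)
class MontageSpec:
    """Channel labels and unit-sphere template positions.

    Attributes
    ----------
    labels : tuple of str
        The 29 scalp channel names, ordered.
    positions : dict
        Label -> 3-D unit vector (template 10-05 position, normalised).
    reference_label : str
        Online reference electrode (not among ``labels``).
    eog_label : str
        Auxiliary ocular channel name (not among ``labels``).
    """

    labels: tuple[str, ...]
    positions: dict[str, np.ndarray] = field(repr=False)
    reference_label: str = REFERENCE_LABEL
    eog_label: str = EOG_LABEL

    def __post_init__(self) -> None:
        if len(self.labels) != 29 or len(set(self.labels)) != 29:
            raise ValueError("montage requires exactly 29 unique scalp labels")
        for lab in self.labels:
            pos = self.positions[lab]
            if abs(np.linalg.norm(pos) - 1.0) > 1e-9:
                raise ValueError(f"position of {lab} is not on the unit sphere")
        if self.reference_label in self.labels or self.eog_label in self.labels:
            raise ValueError("reference/EOG labels must not be scalp labels")

    @property
    def retained_labels(self) -> tuple[str, ...]:
        """Scalp labels kept for analysis (TP9/TP10 dropped): 27 channels."""
        return tuple(l for l in self.labels if l not in EXCLUDED_LABELS)

    def position_array(self, labels: tuple[str, ...] | None = None) -> np.ndarray:
        labels = self.labels if labels is None else labels
        return np.array([self.positions[l] for l in labels])


@lru_cache(maxsize=1)
def generate_montage() -> MontageSpec:
    """Return the fixed 29-channel montage with template 10-05 positions.

    Deterministic; positions are normalised to unit norm so that only the
    angular layout (which drives neighbourhoods and weight maps) matters.
    """
    import mne

    std = mne.channels.make_standard_montage("colin27_1005")
    ch_pos = std.get_positions()["ch_pos"]
    positions: dict[str, np.ndarray] = {}
    for lab in SCALP_LABELS:
        v = np.asarray(ch_pos[lab], dtype=float)
        positions[lab] = v / np.linalg.norm(v)
    return MontageSpec(labels=SCALP_LABELS, positions=positions)


def project_2d(positions: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of unit-sphere points to the plane.

    The vertex (z = +1) maps to the origin; arc distance from the vertex is
    preserved, which keeps the 10-20 ring structure intact for Delaunay
    neighbourhoods.
    """
    pos = np.asarray(positions, dtype=float)
    z = np.clip(pos[:, 2], -1.0, 1.0)
    theta = np.arccos(z)
    xy = pos[:, :2]
    norm = np.linalg.norm(xy, axis=1)
    norm = np.where(norm < 1e-12, 1.0, norm)
    return theta[:, None] * xy / norm[:, None]


@lru_cache(maxsize=8)
def neighbor_adjacency(labels: tuple[str, ...]) -> dict[str, tuple[str, ...]]:
    """Delaunay adjacency of the given electrodes on the 2-D projected layout.

    Deterministic for fixed labels; used both for channel repair (unweighted
    neighbour averaging) and as the cluster-permutation neighbour graph.
    """
    from scipy.spatial import Delaunay

    if len(labels) < 3:
        raise ValueError("need at least 3 electrodes for a neighbour graph")
    montage = generate_montage()
    pts = project_2d(montage.position_array(labels))
    tri = Delaunay(pts)
    adj: dict[str, set[str]] = {l: set() for l in labels}
    for simplex in tri.simplices:
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = labels[simplex[i]], labels[simplex[j]]
                adj[a].add(b)
                adj[b].add(a)
    return {l: tuple(sorted(adj[l])) for l in labels}


#: Frontal weighting map for the blink template: weight decays with arc
#: distance from a point just above the nasion (between Fp1/Fp2).
def frontal_weights(montage: MontageSpec, labels: tuple[str, ...] | None = None) -> np.ndarray:
    labels = montage.labels if labels is None else labels
    anterior = montage.positions["Fp1"] + montage.positions["Fp2"]
    anterior = anterior / np.linalg.norm(anterior)
    pos = montage.position_array(labels)
    arc = np.arccos(np.clip(pos @ anterior, -1.0, 1.0))
    return np.exp(-((arc / 0.9) ** 2))


def posterior_weights(montage: MontageSpec, labels: tuple[str, ...] | None = None) -> np.ndarray:
    """Occipital-dominant weighting used for the alpha rhythm's topography."""
    labels = montage.labels if labels is None else labels
    posterior = montage.positions["O1"] + montage.positions["O2"]
    posterior = posterior / np.linalg.norm(posterior)
    pos = montage.position_array(labels)
    arc = np.arccos(np.clip(pos @ posterior, -1.0, 1.0))
    return 0.25 + 0.75 * np.exp(-((arc / 1.1) ** 2))
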