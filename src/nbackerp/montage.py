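"""Electrode montage: 64-channel BioSemi 10-10 layout plus EOG/mastoid auxiliaries.

Scalp positions are taken from MNE's standard BioSemi-64 template and projected
onto the unit sphere, which is all the downstream code needs: spatial weighting
of simulated sources and interpolation weights are both defined in terms of
great-circle (geodesic) distance between electrode directions.

Four regions of interest are defined for topographic analysis, each a centroid
electrode (F3, F4, P3, P4) plus its six nearest neighbours, giving the
left/right x frontal/parietal quadrants used in the topographic ANCOVAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Auxiliary (non-scalp) channels: vertical/horizontal EOG and the two mastoids.
AUX_CHANNELS = ("VEOG", "HEOG", "M1", "M2")

#: Topographic regions: centroid electrode first, then its 6 nearest neighbours.
ROI_CHANNELS = {
    "left frontal": ("F3", "AF3", "F5", "F1", "FC5", "FC3", "FC1"),
    "right frontal": ("F4", "AF4", "F6", "F2", "FC6", "FC4", "FC2"),
    "left parietal": ("P3", "PO3", "P5", "P1", "CP5", "CP3", "CP1"),
    "right parietal": ("P4", "PO4", "P6", "P2", "CP6", "CP4", "CP2"),
}


@dataclass(frozen=True)
class Montage:
    """Channel labels, unit-sphere scalp positions, and the topographic ROIs.

    Attributes
    ----------
    labels : tuple of str
        All channel names: 64 scalp channels followed by the auxiliaries.
    positions : dict
        Scalp channel -> 3D unit vector (auxiliaries carry no position).
    roi_map : dict
        Region name -> tuple of 7 channel labels (centroid first).
    """

    labels: tuple[str, ...]
    positions: dict[str, np.ndarray] = field(repr=False)
    roi_map: dict[str, tuple[str, ...]]

    @property
    def scalp_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l not in AUX_CHANNELS)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def scalp_index(self, label: str) -> int:
        """Index of ``label`` within the scalp-only channel ordering."""
        return self.scalp_labels.index(label)

    def position_matrix(self, labels: list[str] | tuple[str, ...] | None = None) -> np.ndarray:
        labels = self.scalp_labels if labels is None else labels
        return np.array([self.positions[l] for l in labels])

    def geodesic_distances(self, label: str, labels=None) -> np.ndarray:
        """Great-circle distance (radians) from ``label`` to each scalp channel."""
        p = self.positions[label]
        mat = self.position_matrix(labels)
        cos = np.clip(mat @ p, -1.0, 1.0)
        return np.arccos(cos)


def make_montage(config: dict | None = None) -> Montage:
    """Build the default montage: BioSemi-64 scalp layout + VEOG/HEOG/M1/M2.

    Parameters
    ----------
    config : dict, optional
        Currently supports ``roi_map`` to override the region definitions
        (each region must still hold exactly 7 known scalp channels).
    """
    import mne

    config = config or {}
    std = mne.channels.make_standard_montage("biosemi64")
    ch_pos = std.get_positions()["ch_pos"]
    positions = {}
    for name, pos in ch_pos.items():
        v = np.asarray(pos, dtype=float)
        positions[name] = v / np.linalg.norm(v)
    scalp = tuple(std.ch_names)
    roi_map = {k: tuple(v) for k, v in config.get("roi_map", ROI_CHANNELS).items()}
    for region, chans in roi_map.items():
        if len(set(chans)) != 7:
            raise ValueError(f"ROI {region!r} must contain exactly 7 distinct channels")
        missing = set(chans) - set(scalp)
        if missing:
            raise ValueError(f"ROI {region!r} names unknown channels: {sorted(missing)}")
    return Montage(labels=scalp + AUX_CHANNELS, positions=positions, roi_map=roi_map)
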