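"""64-channel actiCAP-style 10-10 montage: labels, positions, neighbours, posterior ROI.

Positions come from the standard 10-05 template bundled with MNE and are only
used for synthetic scalp weighting and nearest-neighbour channel repair; no
volume conduction model is implied.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Brain Products actiCAP 64-channel layout (TP9 was the online reference in
#: the emulated recording; it still appears here as a data channel).
CHANNELS_64 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FCz", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "PO4", "PO8",
]

#: Posterior left/right electrode pairs used for the alpha-lateralisation ROI.
ROI_PAIRS = [
    ("TP9", "TP10"), ("TP7", "TP8"), ("CP5", "CP6"), ("CP3", "CP4"),
    ("CP1", "CP2"), ("P7", "P8"), ("P5", "P6"), ("P3", "P4"),
    ("P1", "P2"), ("PO7", "PO8"), ("PO3", "PO4"), ("O1", "O2"),
]

ROI_LEFT = [left for left, _ in ROI_PAIRS]
ROI_RIGHT = [right for _, right in ROI_PAIRS]

#: Same-row neighbours (left, right) of midline / fronto-central electrodes,
#: used to expand an ERP peak electrode into its analysis electrode set.
ROW_NEIGHBOURS = {
    "Fz": ("F1", "F2"),
    "FCz": ("FC1", "FC2"),
    "Cz": ("C1", "C2"),
    "CPz": ("CP1", "CP2"),
    "Pz": ("P1", "P2"),
    "Oz": ("O1", "O2"),
    "F1": ("F3", "Fz"),
    "F2": ("Fz", "F4"),
    "FC1": ("FC3", "FCz"),
    "FC2": ("FCz", "FC4"),
    "C1": ("C3", "Cz"),
    "C2": ("Cz", "C4"),
}

MASTOIDS = ("TP9", "TP10")


@lru_cache(maxsize=1)
def channel_positions() -> dict[str, np.ndarray]:
    """3-D head-surface positions (metres) for every channel in CHANNELS_64."""
    import mne

    try:
        template = mne.channels.make_standard_montage("colin27_1005")
    except ValueError:  # older MNE releases ship the template under this name
        template = mne.channels.make_standard_montage("standard_1005")
    pos = template.get_positions()["ch_pos"]
    return {ch: np.asarray(pos[ch], dtype=float) for ch in CHANNELS_64}


def spatial_profile(centre: str, sigma_m: float, channels: list[str] | None = None) -> np.ndarray:
    """Gaussian scalp weighting centred on ``centre``, evaluated per channel.

    Weight 1 at the centre electrode, decaying with 3-D electrode distance.
    """
    channels = list(channels) if channels is not None else CHANNELS_64
    pos = channel_positions()
    c = pos[centre]
    d = np.array([np.linalg.norm(pos[ch] - c) for ch in channels])
    return np.exp(-0.5 * (d / sigma_m) ** 2)


def hemisphere_signs(channels: list[str] | None = None) -> np.ndarray:
    """-1 for left-hemisphere channels, +1 for right, 0 for midline."""
    channels = list(channels) if channels is not None else CHANNELS_64
    pos = channel_positions()
    x = np.array([pos[ch][0] for ch in channels])
    return np.sign(np.where(np.abs(x) < 0.01, 0.0, x))


def nearest_neighbours(channel: str, k: int = 4, channels: list[str] | None = None) -> list[str]:
    """The ``k`` spatially closest other channels (for bad-channel repair)."""
    channels = list(channels) if channels is not None else CHANNELS_64
    pos = channel_positions()
    c = pos[channel]
    others = [ch for ch in channels if ch != channel]
    others.sort(key=lambda ch: np.linalg.norm(pos[ch] - c))
    return others[:k]
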