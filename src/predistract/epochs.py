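"""Epoched EEG container (trials x channels x samples) with trial metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd


@dataclass
class EpochSet:
    """Epoched data in microvolts with a uniform time axis and metadata.

    ``metadata`` has one row per trial (aligned with axis 0 of ``data``) and
    carries the block condition fields plus a boolean ``retained`` column that
    downstream analyses respect. ``reference`` tracks the referencing state
    ("recorded", "average" or "mastoids").
    """

    data: np.ndarray               # (n_trials, n_channels, n_samples), microvolts
    times: np.ndarray              # seconds, uniform
    channels: list[str]
    sfreq: float
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    reference: str = "recorded"

    def __post_init__(self):
        n, c, s = self.data.shape
        if len(self.channels) != c:
            raise ValueError("channel labels do not match data")
        if len(self.times) != s:
            raise ValueError("time axis does not match data")
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-6):
            raise ValueError("time axis is not uniform at 1/sfreq")
        if len(self.metadata) == 0:
            self.metadata = pd.DataFrame(index=range(n))
        if len(self.metadata) != n:
            raise ValueError("metadata length does not match trial count")
        if "retained" not in self.metadata.columns:
            self.metadata = self.metadata.copy()
            self.metadata["retained"] = True

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.times.copy(), list(self.channels),
                        self.sfreq, self.metadata.copy(), self.reference)

    def pick(self, channels: list[str]) -> "EpochSet":
        """Channel subset, preserving the requested order."""
        idx = [self.channels.index(ch) for ch in channels]
        return EpochSet(self.data[:, idx, :], self.times, list(channels),
                        self.sfreq, self.metadata.copy(), self.reference)

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(self.data[mask], self.times, list(self.channels), self.sfreq,
                        self.metadata.loc[mask].reset_index(drop=True), self.reference)

    def retained(self) -> "EpochSet":
        return self.select_trials(self.metadata["retained"].to_numpy(bool))

    def time_mask(self, t_start: float, t_end: float) -> np.ndarray:
        return (self.times >= t_start - 1e-9) & (self.times <= t_end + 1e-9)


def save_epochs(path, epochs: EpochSet) -> None:
    """Persist to HDF5 (datasets data/times/labels, sampling-rate attribute)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("labels", data=np.array(epochs.channels, dtype="S10"))
        f.attrs["sampling_rate"] = epochs.sfreq
        f.attrs["reference"] = epochs.reference
        meta = f.create_group("metadata")
        for col in epochs.metadata.columns:
            values = epochs.metadata[col].to_numpy()
            if values.dtype == object:
                values = values.astype("S32")
            meta.create_dataset(col, data=values)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        channels = [s.decode() for s in f["labels"][()]]
        sfreq = float(f.attrs["sampling_rate"])
        reference = str(f.attrs.get("reference", "recorded"))
        meta = {}
        for col, ds in f["metadata"].items():
            values = ds[()]
            if values.dtype.kind == "S":
                values = np.array([v.decode() for v in values])
            meta[col] = values
    return EpochSet(data, times, channels, sfreq, pd.DataFrame(meta), reference)
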