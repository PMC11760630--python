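"""Deterministic epoch-level preprocessing.

Zero-phase band-pass filtering (0.1-100 Hz), absolute-amplitude trial
rejection (160 uV), re-referencing (common average or linked mastoids),
baseline correction (-0.2-0 s) and exclusion of the unscoreable block-initial
trials (first trial of 1-back blocks, first two of 2-back blocks).

ICA-based ocular/muscle artefact removal is deliberately not part of this
pipeline: it hinges on visual component selection, and the synthetic data
contain no such artefacts. An optional deterministic flat/high-variance
channel repair stands in for visual bad-channel interpolation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from . import montage
from .epochs import EpochSet

logger = logging.getLogger(__name__)

AMPLITUDE_THRESHOLD_UV = 160.0


def bandpass_filter(epochs: EpochSet, high_pass: float = 0.1,
                    low_pass: float = 100.0, order: int = 8) -> EpochSet:
    """Zero-phase (two-pass Butterworth) band-pass filter.

    The default order gives > 20 dB two-pass attenuation one fifth of an
    octave above the low-pass edge while keeping the pass band flat. A
    low-pass above the Nyquist limit is clipped with a logged warning, so the
    defaults stay usable at reduced sampling rates.
    """
    if not np.all(np.isfinite(epochs.data)):
        raise ValueError("non-finite values in epoch data")
    nyq = epochs.sfreq / 2.0
    if low_pass >= nyq:
        clipped = 0.95 * nyq
        logger.warning("low-pass %.1f Hz >= Nyquist %.1f Hz; clipping to %.1f Hz",
                       low_pass, nyq, clipped)
        low_pass = clipped
    sos = butter(order, [high_pass, low_pass], btype="bandpass", fs=epochs.sfreq,
                 output="sos")
    out = epochs.copy()
    # maximal padding: the 0.1-Hz pole settles slowly relative to a 2-s epoch,
    # and the default padding leaves visible startup transients
    padlen = out.data.shape[-1] - 1
    out.data = sosfiltfilt(sos, out.data, axis=-1, padlen=padlen)
    return out


def reject_amplitude(epochs: EpochSet,
                     threshold: float = AMPLITUDE_THRESHOLD_UV) -> EpochSet:
    """Mark trials whose absolute amplitude exceeds ``threshold`` anywhere."""
    out = epochs.copy()
    peak = np.abs(out.data).max(axis=(1, 2))
    out.metadata["retained"] = out.metadata["retained"].to_numpy(bool) & (peak <= threshold)
    return out


def rereference(epochs: EpochSet, scheme: str = "average") -> EpochSet:
    """Re-reference to the common average or to linked mastoids (TP9/TP10)."""
    out = epochs.copy()
    if scheme == "average":
        out.data = out.data - out.data.mean(axis=1, keepdims=True)
    elif scheme == "mastoids":
        missing = [m for m in montage.MASTOIDS if m not in out.channels]
        if missing:
            raise ValueError(f"mastoid channel(s) {missing} not present")
        idx = [out.channels.index(m) for m in montage.MASTOIDS]
        out.data = out.data - out.data[:, idx, :].mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown reference scheme {scheme!r}")
    out.reference = scheme
    return out


def baseline_correct(epochs: EpochSet, window: tuple = (-0.2, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window``."""
    mask = epochs.time_mask(*window)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=-1, keepdims=True)
    return out


def drop_block_initial_trials(obj):
    """Remove unscoreable trials: index <= memory load n within each block.

    Accepts an EpochSet or a trial table; needs ``trial`` and ``memory_load``
    metadata columns.
    """
    meta = obj.metadata if isinstance(obj, EpochSet) else obj
    keep = meta["trial"].to_numpy() > meta["memory_load"].to_numpy()
    if isinstance(obj, EpochSet):
        return obj.select_trials(keep)
    return obj.loc[keep].reset_index(drop=True)


def repair_bad_channels(epochs: EpochSet, flat_tol: float = 1e-12,
                        variance_ratio: float = 25.0, k: int = 4) -> tuple[EpochSet, list[str]]:
    """Deterministic bad-channel detection and nearest-neighbour repair.

    A channel is bad if it is flat (variance below ``flat_tol``) or its
    variance exceeds ``variance_ratio`` times the median channel variance.
    Bad channels are replaced by the mean of their ``k`` nearest neighbours.
    """
    out = epochs.copy()
    var = out.data.var(axis=(0, 2))
    med = np.median(var)
    bad = [ch for ch, v in zip(out.channels, var)
           if v < flat_tol or (med > 0 and v > variance_ratio * med)]
    for ch in bad:
        neigh = [c for c in montage.nearest_neighbours(ch, k=k, channels=out.channels)
                 if c not in bad]
        if not neigh:
            continue
        idx = [out.channels.index(c) for c in neigh]
        out.data[:, out.channels.index(ch), :] = out.data[:, idx, :].mean(axis=1)
    return out, bad


def provenance_entry(stage: str, **info) -> dict:
    """One JSON-serialisable record for a per-stage sidecar log."""
    return {"stage": stage, **info}
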