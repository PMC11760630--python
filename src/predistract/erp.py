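"""ERP averaging, component-window amplitude extraction, single-trial models.

Component windows: the P2 window is centred on the positive fronto-central
peak of the grand average (peak +/- 25 ms, e.g. 160-210 ms for a 185-ms peak)
at the peak electrode and its two row neighbours (FC1/FCz/FC2); the sustained
frontal negativity is averaged over the fixed 400-800 ms interval at F1/Fz/F2.

Single-trial mean amplitudes are regressed on effect-coded (-0.5/+0.5)
condition factors, their interactions, and a participant random intercept;
each coefficient is reported with its t statistic, Satterthwaite df, p-value
and the standardised partial effect size r = sqrt(t^2/(t^2+df)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import montage
from .epochs import EpochSet
from .lmm import RandomInterceptFit, fit_random_intercept
from .stats import effect_size_r

#: factor -> level coded +0.5 (the other level is -0.5)
EFFECT_CODING = {
    "snr_db": 0,                      # high SNR (0 dB) vs low (-10 dB)
    "memory_load": 2,                 # 2-back vs 1-back
    "predictability": "unpredictable",
    "is_nback": True,                 # n-back target vs non-target
}

FN_WINDOW = (0.400, 0.800)
FN_ELECTRODES = ("F1", "Fz", "F2")


@dataclass(frozen=True)
class ComponentWindow:
    name: str
    t_start: float
    t_end: float
    electrodes: tuple

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")


def average_erp(epochs: EpochSet, by=("snr_db", "memory_load", "predictability")):
    """Per-condition trial-average waveforms over retained trials.

    Returns (averages, counts): ``averages`` maps condition tuples to
    channels x samples arrays, ``counts`` to the number of trials averaged.
    """
    kept = epochs.retained()
    averages, counts = {}, {}
    for key, g in kept.metadata.groupby(list(by), observed=True):
        idx = g.index.to_numpy()
        if len(idx) == 0:
            continue
        averages[key] = kept.data[idx].mean(axis=0)
        counts[key] = len(idx)
    if not averages:
        raise ValueError("no retained trials to average")
    return averages, counts


def grand_average(epochs: EpochSet) -> np.ndarray:
    """Average over all retained trials (channels x samples)."""
    kept = epochs.retained()
    if kept.n_trials == 0:
        raise ValueError("no retained trials")
    return kept.data.mean(axis=0)


def find_component_window(ga: np.ndarray, channels: list[str], times: np.ndarray,
                          name: str = "P2", search: tuple = (0.1, 0.3),
                          polarity: int = 1, half_width: float = 0.025,
                          candidates: tuple = ("Fz", "FCz", "Cz")) -> ComponentWindow:
    """Window and electrode set around the grand-average peak.

    Finds the extremum of ``polarity`` sign within ``search`` across the
    candidate (midline) electrodes, snaps the peak latency to the sample grid,
    and returns peak +/- ``half_width`` with the peak electrode and its two
    same-row neighbours.
    """
    mask = (times >= search[0]) & (times <= search[1])
    if not mask.any():
        raise ValueError("search range contains no samples")
    cand_idx = [channels.index(ch) for ch in candidates if ch in channels]
    if not cand_idx:
        raise ValueError("no candidate electrodes present")
    seg = polarity * ga[np.ix_(cand_idx, np.flatnonzero(mask))]
    if seg.max() <= 0:
        raise ValueError(f"no {'positive' if polarity > 0 else 'negative'} "
                         "deflection in the search range")
    ch_pos, t_pos = np.unravel_index(np.argmax(seg), seg.shape)
    peak_channel = channels[cand_idx[ch_pos]]
    peak_time = times[np.flatnonzero(mask)[t_pos]]
    left, right = montage.ROW_NEIGHBOURS[peak_channel]
    return ComponentWindow(name, round(peak_time - half_width, 6),
                           round(peak_time + half_width, 6),
                           (left, peak_channel, right))


def fn_component_window() -> ComponentWindow:
    """The fixed sustained frontal-negativity window (400-800 ms, F1/Fz/F2)."""
    return ComponentWindow("frontal_negativity", *FN_WINDOW, FN_ELECTRODES)


def single_trial_amplitude(epochs: EpochSet, window: ComponentWindow) -> pd.DataFrame:
    """Mean amplitude over the window's samples and electrodes, per trial.

    Only retained trials are returned; the trial's condition metadata rides
    along so the result feeds the mixed model directly.
    """
    missing = [ch for ch in window.electrodes if ch not in epochs.channels]
    if missing:
        raise ValueError(f"electrodes {missing} not in epochs")
    tmask = epochs.time_mask(window.t_start, window.t_end)
    if not tmask.any():
        raise ValueError("window lies outside the epoch")
    kept = epochs.retained()
    idx = [kept.channels.index(ch) for ch in window.electrodes]
    amp = kept.data[:, idx, :][:, :, tmask].mean(axis=(1, 2))
    out = kept.metadata.copy()
    out["amplitude"] = amp
    return out


def effect_code(meta: pd.DataFrame, factor: str) -> np.ndarray:
    """-0.5/+0.5 coding; the level coded +0.5 is fixed in EFFECT_CODING."""
    high = EFFECT_CODING[factor]
    return np.where(meta[factor].to_numpy() == high, 0.5, -0.5)


def build_design(meta: pd.DataFrame,
                 factors=("snr_db", "memory_load", "predictability"),
                 interactions: bool = True):
    """Effect-coded design matrix with intercept and (optionally) all interactions."""
    cols = {"intercept": np.ones(len(meta))}
    coded = {f: effect_code(meta, f) for f in factors}
    for f in factors:
        cols[f] = coded[f]
    if interactions:
        for k in range(2, len(factors) + 1):
            for combo in itertools.combinations(factors, k):
                cols[" x ".join(combo)] = np.prod([coded[f] for f in combo], axis=0)
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys())


def fit_component_lmm(amplitudes: pd.DataFrame, dv: str = "amplitude",
                      participant: str = "participant",
                      factors=("snr_db", "memory_load", "predictability"),
                      interactions: bool = True) -> tuple[pd.DataFrame, RandomInterceptFit]:
    """Single-trial LMM: dv ~ factors (+ interactions) + (1 | participant).

    Returns (summary table, fit). The summary has one row per fixed-effect
    term with estimate, t, Satterthwaite df, p and effect size r. Sub-group
    refits (e.g. within one load level) are just calls on a filtered table
    with fewer factors. A singular fit (zero participant variance) is
    reported via ``fit.singular``, not hidden.
    """
    if amplitudes[participant].nunique() < 2:
        raise ValueError("need at least two participants for a random intercept")
    for f in factors:
        if amplitudes[f].nunique() < 2:
            raise ValueError(f"factor {f} does not vary")
    X, terms = build_design(amplitudes, factors, interactions)
    fit = fit_random_intercept(X, amplitudes[dv].to_numpy(),
                               amplitudes[participant].to_numpy(), terms)
    table = fit.summary_frame()
    table["r"] = [effect_size_r(t, df) for t, df in zip(table["t"], table["df"])]
    return table, fit
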