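"""Time-frequency power and alpha-lateralisation indices.

Power comes from a moving-window FFT (500-ms Hanning taper, evaluated from
-0.7 to 0.7 s in 50-ms steps, 1-50 Hz in 1-Hz steps). A 500-ms window has
2-Hz native resolution; the 1-Hz grid is obtained by zero-padding the tapered
segment to 1 s, which interpolates between native bins.

Two indices quantify spatial attention from band-limited power:

* AMI = (Pow_attend-left - Pow_attend-right) / (Pow_attend-left + Pow_attend-right),
  per channel/frequency/time, from trial-averaged power of the two attention
  directions;
* ALI = (Pow_ipsi - Pow_contra) / (Pow_ipsi + Pow_contra), after averaging
  8-12 Hz power over the posterior ROI electrodes of each hemisphere
  (ipsi/contra assigned per attended side). Positive ALI = the typical
  higher-ipsilateral alpha pattern.

Power is averaged over trials (and over ROI and band) before any ratio is
taken: the indices are ratios of averaged power, not averages of ratios.
Window selection runs a paired t-test of left- vs right-hemisphere AMI at
every time point across subjects, applies Benjamini-Hochberg FDR over time
points, and returns contiguous significant runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel

from .epochs import EpochSet
from .montage import ROI_LEFT, ROI_PAIRS, ROI_RIGHT
from .stats import fdr_bh, rm_anova

DEFAULT_FOI = np.arange(1, 51, dtype=float)
DEFAULT_TOI = np.round(np.arange(-0.7, 0.7001, 0.05), 10)
ALPHA_BAND = (8.0, 12.0)
WINDOW_S = 0.5
T1 = (-0.5, -0.35)
T2 = (0.3, 0.5)


def tfr_power(data: np.ndarray, times: np.ndarray, sfreq: float,
              foi=DEFAULT_FOI, toi=DEFAULT_TOI, window: float = WINDOW_S,
              precision: str = "single") -> np.ndarray:
    """Moving-window Hanning-taper power of (trials, channels, samples) data.

    Returns absolute power (mean-square amplitude, uV^2) with shape
    (trials, channels, len(foi), len(toi)). Raises if any requested time
    point's window exceeds the epoch bounds, or a frequency is not resolvable.
    ``precision`` controls the inner products ("single" is ample for
    physiological dynamic range; "double" for numerical studies).
    """
    foi = np.asarray(foi, dtype=float)
    toi = np.asarray(toi, dtype=float)
    win_len = int(round(window * sfreq))
    nfft = int(round(sfreq))           # zero-pad to 1 s -> 1-Hz bin spacing
    bins = np.round(foi * nfft / sfreq).astype(int)
    if np.any(foi >= sfreq / 2):
        raise ValueError("requested frequency at or above Nyquist")
    taper = np.hanning(win_len)
    scale = 2.0 / taper.sum()
    half = window / 2.0
    # evaluating a handful of bins via a direct DFT matmul beats a full FFT
    few_bins = len(bins) * 4 < nfft
    real_dtype = np.float32 if precision == "single" else np.float64
    cplx_dtype = np.complex64 if precision == "single" else np.complex128
    if few_bins:
        dft = np.exp(-2j * np.pi * np.outer(np.arange(win_len), bins) / nfft)
        dft = (taper[:, None] * dft).astype(cplx_dtype)
    out = np.empty(data.shape[:2] + (len(foi), len(toi)))
    for ti, t0 in enumerate(toi):
        start = int(round((t0 - half - times[0]) * sfreq))
        if start < 0 or start + win_len > data.shape[-1]:
            raise ValueError(f"window at t={t0:g}s exceeds the epoch bounds")
        if few_bins:
            seg = np.ascontiguousarray(data[:, :, start:start + win_len],
                                       dtype=real_dtype)
            amp = scale * np.abs(seg @ dft)
        else:
            seg = data[:, :, start:start + win_len] * taper
            spec = np.fft.rfft(seg, n=nfft, axis=-1)
            amp = scale * np.abs(spec[:, :, bins])
        out[:, :, :, ti] = 0.5 * amp.astype(np.float64) ** 2
    return out


def condition_power(epochs: EpochSet, by=("snr_db", "memory_load", "predictability",
                                          "attend_side"),
                    picks: list[str] | None = None, foi=DEFAULT_FOI,
                    toi=DEFAULT_TOI, window: float = WINDOW_S):
    """Trial-averaged power per condition group over retained trials.

    Returns (powers, channels, counts): ``powers`` maps group keys to
    channels x frequencies x times arrays, ``counts`` to the number of trials
    averaged. Power is computed per trial and averaged within each group
    (time point by time point, to bound memory).
    """
    kept = epochs.retained()
    if picks is not None:
        kept = kept.pick(picks)
    groups = {(key if isinstance(key, tuple) else (key,)): idx.to_numpy()
              for key, idx in
              kept.metadata.groupby(list(by), observed=True).groups.items()}
    foi = np.asarray(foi, dtype=float)
    toi = np.asarray(toi, dtype=float)
    powers = {key: np.empty((len(kept.channels), len(foi), len(toi)))
              for key in groups}
    for ti, t0 in enumerate(toi):
        p = tfr_power(kept.data, kept.times, kept.sfreq, foi, np.array([t0]), window)
        for key, idx in groups.items():
            powers[key][:, :, ti] = p[idx, :, :, 0].mean(axis=0)
    counts = {key: len(idx) for key, idx in groups.items()}
    return powers, list(kept.channels), counts


def aggregate_powers(powers: dict, counts: dict, key_fn):
    """Re-group trial-averaged powers by a coarser key (count-weighted mean)."""
    sums: dict = {}
    totals: dict = {}
    for key, p in powers.items():
        new = key_fn(key)
        n = counts[key]
        if new in sums:
            sums[new] = sums[new] + n * p
            totals[new] += n
        else:
            sums[new] = n * p
            totals[new] = n
    return {k: sums[k] / totals[k] for k in sums}, totals


def compute_ami(pow_attend_left: np.ndarray, pow_attend_right: np.ndarray) -> np.ndarray:
    """Attentional modulation index, elementwise (L - R) / (L + R).

    Entries where both inputs are zero are returned as NaN (undefined).
    """
    left = np.asarray(pow_attend_left, dtype=float)
    right = np.asarray(pow_attend_right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("power arrays must share a shape")
    if np.any(left < 0) or np.any(right < 0):
        raise ValueError("power must be non-negative")
    denom = left + right
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (left - right) / denom, np.nan)


def _band_mask(foi, band) -> np.ndarray:
    foi = np.asarray(foi, dtype=float)
    mask = (foi >= band[0]) & (foi <= band[1])
    if not mask.any():
        raise ValueError("frequency band not covered by the frequency axis")
    return mask


def compute_ali(power: np.ndarray, channels: list[str], attend_side: str,
                roi_pairs=ROI_PAIRS, band=ALPHA_BAND, foi=DEFAULT_FOI) -> np.ndarray:
    """Time-resolved alpha lateralisation index from one condition's power.

    ``power`` is channels x frequencies x times (trial-averaged). Power is
    first averaged over the band and over each hemisphere's ROI electrodes,
    then the ipsi/contra ratio index is formed per time point.
    """
    left_names = [l for l, _ in roi_pairs]
    right_names = [r for _, r in roi_pairs]
    missing = [ch for ch in left_names + right_names if ch not in channels]
    if missing:
        raise ValueError(f"ROI channel(s) {missing} not present")
    fmask = _band_mask(foi, band)
    li = [channels.index(ch) for ch in left_names]
    ri = [channels.index(ch) for ch in right_names]
    p_left = power[li][:, fmask, :].mean(axis=(0, 1))
    p_right = power[ri][:, fmask, :].mean(axis=(0, 1))
    if attend_side == "left":
        p_ipsi, p_contra = p_left, p_right
    elif attend_side == "right":
        p_ipsi, p_contra = p_right, p_left
    else:
        raise ValueError(f"unknown attend_side {attend_side!r}")
    return (p_ipsi - p_contra) / (p_ipsi + p_contra)


def subject_ali_table(powers: dict, channels: list[str], participant=0,
                      foi=DEFAULT_FOI, toi=DEFAULT_TOI,
                      windows={"T1": T1, "T2": T2}) -> pd.DataFrame:
    """Window-averaged ALI per condition cell for one subject.

    ``powers`` is the output of :func:`condition_power` grouped by
    (snr_db, memory_load, predictability, attend_side); the ALI series of the
    two attended sides of a cell are averaged before window averaging.
    """
    toi = np.asarray(toi, dtype=float)
    series: dict[tuple, list] = {}
    for (snr, load, pred, side), p in powers.items():
        ali = compute_ali(p, channels, side, foi=foi)
        series.setdefault((snr, load, pred), []).append(ali)
    rows = []
    for (snr, load, pred), parts in series.items():
        ali = np.mean(parts, axis=0)
        for name, (t0, t1) in windows.items():
            wmask = (toi >= t0 - 1e-9) & (toi <= t1 + 1e-9)
            rows.append({"participant": participant, "snr_db": snr,
                         "memory_load": load, "predictability": pred,
                         "window": name, "ali": float(ali[wmask].mean())})
    return pd.DataFrame(rows)


def roi_ami_series(powers_by_side: dict, channels: list[str],
                   foi=DEFAULT_FOI, band=ALPHA_BAND) -> tuple[np.ndarray, np.ndarray]:
    """Alpha-band AMI averaged over left vs right ROI electrodes.

    ``powers_by_side`` maps "left"/"right" (attended side) to trial-averaged
    channels x frequencies x times power. Returns (left_series, right_series)
    over time, the inputs to window selection.
    """
    ami = compute_ami(powers_by_side["left"], powers_by_side["right"])
    fmask = _band_mask(foi, band)
    li = [channels.index(ch) for ch in ROI_LEFT]
    ri = [channels.index(ch) for ch in ROI_RIGHT]
    return (ami[li][:, fmask, :].mean(axis=(0, 1)),
            ami[ri][:, fmask, :].mean(axis=(0, 1)))


@dataclass
class WindowSelection:
    times: np.ndarray
    pvalues: np.ndarray
    mask: np.ndarray                       # FDR-significant time points
    windows: list                          # contiguous (t_start, t_end) runs

    def covers(self, t_start: float, t_end: float) -> bool:
        return any(w0 <= t_start + 1e-9 and w1 >= t_end - 1e-9
                   for w0, w1 in self.windows)


def select_windows(ami_left: np.ndarray, ami_right: np.ndarray,
                   times=DEFAULT_TOI, alpha: float = 0.05) -> WindowSelection:
    """FDR-corrected time windows where left and right ROI AMI diverge.

    ``ami_left``/``ami_right`` are subjects x times; a paired t-test runs at
    each time point, Benjamini-Hochberg correction runs across time points,
    and maximal contiguous runs of significant points become windows.
    """
    left = np.atleast_2d(np.asarray(ami_left, dtype=float))
    right = np.atleast_2d(np.asarray(ami_right, dtype=float))
    times = np.asarray(times, dtype=float)
    if left.shape != right.shape or left.shape[1] != len(times):
        raise ValueError("AMI arrays must be subjects x times, matching the time axis")
    if left.shape[0] < 2:
        raise ValueError("window selection needs at least two subjects")
    pvals = ttest_rel(left, right, axis=0).pvalue
    mask = fdr_bh(pvals, q=alpha)
    windows, start = [], None
    for i, sig in enumerate(mask):
        if sig and start is None:
            start = i
        if (not sig or i == len(mask) - 1) and start is not None:
            end = i if sig else i - 1
            windows.append((float(times[start]), float(times[end])))
            start = None
    return WindowSelection(times=times, pvalues=pvals, mask=mask, windows=windows)


def ali_window_anova(table: pd.DataFrame):
    """2x2x2x2 within-subject ANOVA on window-averaged ALI, plus follow-ups.

    ``table`` needs columns participant, snr_db, memory_load, predictability,
    window and ali. Returns (main table, {window: per-window 2x2x2 table}).
    """
    main = rm_anova(table, dv="ali", subject="participant",
                    within=["snr_db", "memory_load", "window", "predictability"])
    follow = {}
    for name, g in table.groupby("window", observed=True):
        follow[name] = rm_anova(g, dv="ali", subject="participant",
                                within=["snr_db", "memory_load", "predictability"])
    return main, follow
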