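"""Synthetic behaviour and EEG with known ground truth.

Stands in for raw recordings of the dual-stream spatial n-back study. The
generator injects, per condition cell:

* button presses from a signal-detection model with per-cell sensitivity d'
  and criterion c (press probability Phi(d'/2 - c) on n-back targets and
  Phi(-d'/2 - c) on non-targets);
* 64-channel epoched EEG (-1..1 s around pair onset) built from 1/f noise,
  a ~10-Hz posterior alpha oscillation whose hemispheric gains realise a
  configurable lateralisation index per time window, and evoked components
  (P1, N1, a fronto-central P2 and a sustained frontal negativity) with
  condition-dependent amplitudes.

Alpha lateralisation is a multiplicative per-hemisphere amplitude gain
g_ipsi = sqrt(1 + a), g_contra = sqrt(1 - a), so the power-based index
(P_ipsi - P_contra) / (P_ipsi + P_contra) of the noise-free oscillation equals
the configured ``a`` exactly. The gain plateau extends half a spectral-analysis
window (0.25 s) beyond each configured time window, with raised-cosine ramps,
so that a moving-window power estimate centred anywhere inside the window sees
the full plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import montage
from .design import CONDITION_CELLS, ExperimentPlan
from .epochs import EpochSet

# ---------------------------------------------------------------------------
# behaviour


@dataclass(frozen=True)
class BehaviorParams:
    """Generative d' and criterion per (snr_db, memory_load, predictability)."""

    dprime: dict
    criterion: dict

    def __post_init__(self):
        for cell in CONDITION_CELLS:
            if cell not in self.dprime or cell not in self.criterion:
                raise ValueError(f"missing behaviour parameters for cell {cell}")
            if self.dprime[cell] < 0:
                raise ValueError("generative d' must be non-negative")

    def press_probabilities(self, cell) -> tuple[float, float]:
        d, c = self.dprime[cell], self.criterion[cell]
        return float(norm.cdf(d / 2 - c)), float(norm.cdf(-d / 2 - c))


def default_behavior_params() -> BehaviorParams:
    """Plausible per-cell SDT parameters.

    Sensitivity is high overall and lower under the 2-back load; responding is
    conservative (positive c), more so under high memory load, and least
    conservative in the easiest cell (0 dB SNR, 1-back, predictable).
    """
    dprime, criterion = {}, {}
    for snr, load, pred in CONDITION_CELLS:
        dprime[(snr, load, pred)] = 3.0 if load == 1 else 2.2
        c = 0.40 + (0.25 if load == 2 else 0.0)
        if (snr, load, pred) == (0, 1, "predictable"):
            c = 0.25
        criterion[(snr, load, pred)] = c
    return BehaviorParams(dprime=dprime, criterion=criterion)


def simulate_responses(plan: ExperimentPlan, params: BehaviorParams, seed) -> pd.DataFrame:
    """Per-trial press log (block, trial, pressed, rt_s).

    Presses are Bernoulli with the cell's SDT probabilities; reaction times are
    uniform in (0, 2] and absent for non-presses.
    """
    rng = np.random.default_rng(seed)
    trials = plan.to_frame()
    p = np.empty(len(trials))
    for cell, g in trials.groupby(["snr_db", "memory_load", "predictability"], observed=True):
        p_hit, p_fa = params.press_probabilities(cell)
        p[g.index] = np.where(g["is_nback"], p_hit, p_fa)
    pressed = rng.random(len(trials)) < p
    rt = np.where(pressed, 2.0 - rng.random(len(trials)) * 2.0, np.nan)  # uniform (0, 2]
    return pd.DataFrame({
        "block": trials["block"], "trial": trials["trial"],
        "pressed": pressed, "rt_s": rt,
    })


# ---------------------------------------------------------------------------
# EEG


@dataclass(frozen=True)
class ErpComponent:
    """One evoked deflection: Gaussian pulse or sustained (ramped boxcar).

    ``effects`` maps condition predicates to additive amplitude deltas
    (microvolts). A predicate is "field==value" or a "&"-joined conjunction;
    the bare key "is_nback" addresses target trials.
    """

    name: str
    amplitude: float                 # base peak amplitude, microvolts
    centre: str                      # electrode of the spatial maximum
    spatial_sigma: float = 0.06      # metres
    latency: float | None = None     # Gaussian pulse peak, seconds
    width: float | None = None       # Gaussian pulse SD, seconds
    window: tuple | None = None      # sustained component extent, seconds
    effects: dict = field(default_factory=dict)

    def time_course(self, times: np.ndarray) -> np.ndarray:
        if self.window is not None:
            t0, t1 = self.window
            ramp = 0.05
            up = np.clip((times - t0) / ramp, 0, 1)
            down = np.clip((t1 - times) / ramp, 0, 1)
            tc = (0.5 - 0.5 * np.cos(np.pi * up)) * (0.5 - 0.5 * np.cos(np.pi * down))
            return np.where((times >= t0) & (times <= t1), tc, 0.0)
        return np.exp(-0.5 * ((times - self.latency) / self.width) ** 2)

    def trial_amplitudes(self, meta: pd.DataFrame) -> np.ndarray:
        amp = np.full(len(meta), self.amplitude)
        for key, delta in self.effects.items():
            mask = np.ones(len(meta), dtype=bool)
            for clause in key.split("&"):
                if clause == "is_nback":
                    mask &= meta["is_nback"].to_numpy(bool)
                else:
                    fieldname, value = clause.split("==")
                    mask &= meta[fieldname].astype(str).to_numpy() == value
            amp[mask] += delta
        return amp


def default_erp_components() -> list[ErpComponent]:
    """Obligatory P1/N1, a condition-sensitive P2 and a frontal negativity.

    Signs of the injected condition effects follow the study's findings:
    larger P2 for high SNR, 2-back and unpredictable distractors (and smaller
    on n-back targets); a frontal negativity whose magnitude grows with high
    SNR and low memory load, with predictability deepening it under low load
    and weakly reversing under high load.
    """
    return [
        ErpComponent("P1", amplitude=2.0, centre="Cz", latency=0.050, width=0.015),
        ErpComponent("N1", amplitude=-4.0, centre="FCz", latency=0.100, width=0.020),
        ErpComponent("P2", amplitude=3.0, centre="FCz", latency=0.185, width=0.022,
                     effects={
                         "snr_db==0": 0.5,
                         "memory_load==2": 0.2,
                         "predictability==unpredictable": 0.4,
                         "is_nback": -0.3,
                     }),
        ErpComponent("frontal_negativity", amplitude=-1.5, centre="Fz", window=(0.4, 0.8),
                     effects={
                         "snr_db==0": -0.4,
                         "memory_load==1": -0.5,
                         "memory_load==1&predictability==predictable": -0.3,
                         "memory_load==2&predictability==predictable": 0.2,
                     }),
    ]


def default_ali_true() -> dict:
    """Target lateralisation index per (window, predictability).

    T1 (pre-stimulus): sign-reversed lateralisation for unpredictable
    distractors only; T2 (post-stimulus): the typical positive lateralisation
    for both predictability levels.
    """
    return {
        ("T1", "predictable"): 0.0,
        ("T1", "unpredictable"): -0.1,
        ("T2", "predictable"): 0.2,
        ("T2", "unpredictable"): 0.2,
    }


@dataclass(frozen=True)
class EEGParams:
    """Generator settings for the epoched synthetic EEG (units: s, Hz, uV)."""

    sampling_rate: float = 250.0
    channels: tuple = tuple(montage.CHANNELS_64)
    tmin: float = -1.0
    tmax: float = 1.0
    alpha_freq: float = 10.0
    alpha_amp: float = 14.0            # peak oscillation amplitude at the profile centre
    alpha_centres: tuple = ("PO3", "PO4")
    alpha_sigma: float = 0.09          # scalp profile width, metres
    alpha_jitter_sigma: float = 0.2    # log-normal trial-to-trial amplitude jitter
    windows: tuple = (("T1", (-0.5, -0.35)), ("T2", (0.3, 0.5)))
    ali_true: tuple = tuple(sorted(default_ali_true().items()))
    ali_subject_sd: float = 0.05
    smear_pad: float = 0.25            # plateau extension, half a 0.5-s analysis window
    ramp: float = 0.08                 # raised-cosine gain ramp, seconds
    erp_components: tuple = tuple(default_erp_components())
    erp_subject_sd: float = 1.5        # per-subject component amplitude offset, uV
    noise_exponent: float = 1.0        # 1/f slope of the background spectrum
    noise_sd: float = 9.0              # broadband noise SD per channel, uV

    def __post_init__(self):
        if self.sampling_rate <= 2 * self.alpha_freq:
            raise ValueError("sampling rate must exceed twice the alpha frequency")
        for (_, pred), a in self.ali_true:
            if abs(a) >= 1:
                raise ValueError("|ali_true| must be < 1")
        for comp in self.erp_components:
            lo = comp.window[0] if comp.window else comp.latency
            hi = comp.window[1] if comp.window else comp.latency
            if not (self.tmin <= lo and hi <= self.tmax):
                raise ValueError(f"component {comp.name} lies outside the epoch")

    @property
    def ali_map(self) -> dict:
        return dict(self.ali_true)

    @property
    def window_map(self) -> dict:
        return dict(self.windows)


def _ali_curve(times: np.ndarray, targets: dict, windows: dict,
               pad: float, ramp: float) -> np.ndarray:
    """Time-resolved lateralisation target a(t): plateaus with cosine ramps."""
    a = np.zeros_like(times)
    for name, (t0, t1) in windows.items():
        target = targets.get(name, 0.0)
        if target == 0.0:
            continue
        lo, hi = t0 - pad, t1 + pad
        bump = np.zeros_like(times)
        bump[(times >= lo) & (times <= hi)] = 1.0
        up = (times > lo - ramp) & (times < lo)
        bump[up] = 0.5 - 0.5 * np.cos(np.pi * (times[up] - (lo - ramp)) / ramp)
        down = (times > hi) & (times < hi + ramp)
        bump[down] = 0.5 + 0.5 * np.cos(np.pi * (times[down] - hi) / ramp)
        a = a + target * bump
    return np.clip(a, -0.95, 0.95)


def _pink_noise(rng, shape, sfreq, exponent, sd) -> np.ndarray:
    """1/f^exponent Gaussian noise along the last axis, calibrated to ``sd``.

    Computed in single precision (ample for a noise floor) to keep large
    trial x channel x sample tensors cheap.
    """
    from scipy import fft as sfft

    n = shape[-1]
    white = rng.standard_normal(shape, dtype=np.float32)
    spec = sfft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    h = np.zeros_like(f)
    h[1:] = f[1:] ** (-exponent / 2.0)
    gains = np.full_like(f, 2.0)
    gains[0] = 1.0
    if n % 2 == 0:
        gains[-1] = 1.0
    h /= np.sqrt(np.sum(gains * h ** 2) / n)          # unit output variance
    spec *= h.astype(np.complex64)
    return np.asarray(sd * sfft.irfft(spec, n=n, axis=-1), dtype=np.float64)


def simulate_eeg_epochs(plan: ExperimentPlan, params: EEGParams, seed,
                        picks: list[str] | None = None) -> EpochSet:
    """Generate one subject's epoched EEG for every trial of ``plan``.

    ``picks`` restricts the simulated channels (the physics is per-channel, so
    a subset is exact, not an approximation). Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    channels = list(picks) if picks is not None else list(params.channels)
    sfreq = params.sampling_rate
    n_samples = int(round((params.tmax - params.tmin) * sfreq))
    times = params.tmin + np.arange(n_samples) / sfreq
    meta = plan.to_frame()
    n_trials = len(meta)

    data = _pink_noise(rng, (n_trials, len(channels), n_samples), sfreq,
                       params.noise_exponent, params.noise_sd)

    # --- lateralised alpha -------------------------------------------------
    # each hemisphere's oscillator projects onto its own hemisphere's channels
    # only, so per-channel (and pooled) power ratios equal the configured index
    hemi = montage.hemisphere_signs(channels)
    w_left = montage.spatial_profile(params.alpha_centres[0], params.alpha_sigma, channels)
    w_right = montage.spatial_profile(params.alpha_centres[1], params.alpha_sigma, channels)
    w_left = np.where(hemi < 0, w_left, 0.0)
    w_right = np.where(hemi > 0, w_right, 0.0)
    windows = params.window_map
    subject_shift = {name: rng.normal(0.0, params.ali_subject_sd) for name in windows}
    curves = {}
    for pred in ("predictable", "unpredictable"):
        targets = {name: params.ali_map[(name, pred)] + subject_shift[name]
                   for name in windows}
        a = _ali_curve(times, targets, windows, params.smear_pad, params.ramp)
        curves[pred] = (np.sqrt(1 + a), np.sqrt(1 - a))       # (g_ipsi, g_contra)

    jitter = np.exp(rng.normal(0.0, params.alpha_jitter_sigma, n_trials))
    phase_l = rng.uniform(0, 2 * np.pi, n_trials)
    phase_r = rng.uniform(0, 2 * np.pi, n_trials)
    osc_l = np.sin(2 * np.pi * params.alpha_freq * times[None, :] + phase_l[:, None])
    osc_r = np.sin(2 * np.pi * params.alpha_freq * times[None, :] + phase_r[:, None])
    pred_arr = meta["predictability"].to_numpy()
    side_arr = meta["attend_side"].to_numpy()
    g_left = np.empty((n_trials, n_samples))
    g_right = np.empty((n_trials, n_samples))
    for pred in ("predictable", "unpredictable"):
        g_ipsi, g_contra = curves[pred]
        m = (pred_arr == pred) & (side_arr == "left")          # ipsi = left hemisphere
        g_left[m], g_right[m] = g_ipsi, g_contra
        m = (pred_arr == pred) & (side_arr == "right")
        g_left[m], g_right[m] = g_contra, g_ipsi
    amp = params.alpha_amp * jitter
    data += (amp[:, None] * g_left * osc_l)[:, None, :] * w_left[None, :, None]
    data += (amp[:, None] * g_right * osc_r)[:, None, :] * w_right[None, :, None]

    # --- evoked components -------------------------------------------------
    subject_offsets = rng.normal(0.0, params.erp_subject_sd, len(params.erp_components))
    for comp, offset in zip(params.erp_components, subject_offsets):
        w = montage.spatial_profile(comp.centre, comp.spatial_sigma, channels)
        tc = comp.time_course(times)
        amp = comp.trial_amplitudes(meta) + offset
        data += amp[:, None, None] * w[None, :, None] * tc[None, None, :]

    return EpochSet(data, times, channels, sfreq, meta, reference="recorded")


def ground_truth_report(behavior: BehaviorParams, eeg: EEGParams) -> pd.DataFrame:
    """Table of every injected effect, for recovery comparisons."""
    rows = []
    for cell in CONDITION_CELLS:
        snr, load, pred = cell
        rows.append({"kind": "dprime", "name": "dprime",
                     "snr_db": snr, "memory_load": load, "predictability": pred,
                     "value": behavior.dprime[cell]})
        rows.append({"kind": "criterion", "name": "criterion",
                     "snr_db": snr, "memory_load": load, "predictability": pred,
                     "value": behavior.criterion[cell]})
    for (window, pred), a in eeg.ali_map.items():
        rows.append({"kind": "ali", "name": window, "predictability": pred, "value": a})
    for comp in eeg.erp_components:
        rows.append({"kind": "erp_base", "name": comp.name, "value": comp.amplitude})
        for key, delta in comp.effects.items():
            rows.append({"kind": "erp_effect", "name": f"{comp.name}:{key}", "value": delta})
    return pd.DataFrame(rows)
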