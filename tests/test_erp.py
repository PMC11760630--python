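"""ERP averaging, component windows, single-trial amplitudes and their LMM."""

import numpy as np
import pandas as pd
import pytest

from predistract import build_experiment
from predistract.epochs import EpochSet
from predistract.erp import (
    ComponentWindow,
    average_erp,
    find_component_window,
    fit_component_lmm,
    fn_component_window,
    grand_average,
    single_trial_amplitude,
)
from predistract.preprocess import baseline_correct, drop_block_initial_trials, rereference
from predistract.synth import EEGParams, simulate_eeg_epochs
from tests.conftest import make_epochs

CHS = ["F1", "Fz", "F2", "FC1", "FCz", "FC2", "C1", "Cz", "C2"]


def _waveform_epochs(peak_t, peak_channel="FCz", amp=5.0, sfreq=1000.0, n_trials=3):
    ep = make_epochs(n_trials=n_trials, channels=CHS, sfreq=sfreq)
    bump = amp * np.exp(-0.5 * ((ep.times - peak_t) / 0.02) ** 2)
    ep.data[:, CHS.index(peak_channel), :] = bump
    return ep


def test_average_of_identical_epochs_is_any_one(const_epochs):
    const_epochs.data[:] = 3.14
    const_epochs.metadata["snr_db"] = 0
    const_epochs.metadata["memory_load"] = 1
    const_epochs.metadata["predictability"] = "predictable"
    averages, counts = average_erp(const_epochs)
    key = (0, 1, "predictable")
    assert np.allclose(averages[key], 3.14)
    assert counts[key] == const_epochs.n_trials


def test_average_suppresses_zero_mean_noise():
    rng = np.random.default_rng(1)
    ep = make_epochs(n_trials=400)
    ep.data[:] = rng.normal(0, 5, ep.data.shape)
    assert np.abs(grand_average(ep)).max() < 5 * 4.7 / np.sqrt(400)


@pytest.mark.parametrize("peak_ms,expect", [(185, (0.160, 0.210)), (200, (0.175, 0.225))])
def test_component_window_from_peak(peak_ms, expect):
    ep = _waveform_epochs(peak_ms / 1000.0)
    window = find_component_window(grand_average(ep), CHS, ep.times)
    assert (window.t_start, window.t_end) == pytest.approx(expect, abs=1e-9)
    assert window.electrodes == ("FC1", "FCz", "FC2")


def test_component_window_peak_electrode_neighbours():
    ep = _waveform_epochs(0.185, peak_channel="Fz")
    window = find_component_window(grand_average(ep), CHS, ep.times)
    assert window.electrodes == ("F1", "Fz", "F2")


def test_component_window_requires_a_positive_peak():
    ep = make_epochs(channels=CHS)           # flat
    with pytest.raises(ValueError, match="deflection"):
        find_component_window(grand_average(ep), CHS, ep.times)


def test_component_window_validation():
    with pytest.raises(ValueError):
        ComponentWindow("P2", 0.3, 0.2, ("FCz",))
    fn = fn_component_window()
    assert (fn.t_start, fn.t_end) == (0.4, 0.8)
    assert fn.electrodes == ("F1", "Fz", "F2")


def test_single_trial_amplitude_constant_and_subset_mean():
    ep = make_epochs(n_trials=4, channels=CHS, fill=2.5)
    window = ComponentWindow("P2", 0.16, 0.21, ("FC1", "FCz", "FC2"))
    table = single_trial_amplitude(ep, window)
    assert np.allclose(table["amplitude"], 2.5)
    rng = np.random.default_rng(2)
    ep.data[:] = rng.normal(size=ep.data.shape)
    table = single_trial_amplitude(ep, window)
    idx = [CHS.index(c) for c in window.electrodes]
    tmask = ep.time_mask(0.16, 0.21)
    manual = ep.data[:, idx, :][:, :, tmask].mean(axis=(1, 2))
    assert np.allclose(table["amplitude"], manual)
    with pytest.raises(ValueError):
        single_trial_amplitude(ep, ComponentWindow("x", 5.0, 6.0, ("FCz",)))
    with pytest.raises(ValueError):
        single_trial_amplitude(ep, ComponentWindow("x", 0.1, 0.2, ("PO3",)))


def test_amplitude_extraction_is_linear_in_component_gain():
    plan = build_experiment(31, n_trials_per_block=12)
    window = ComponentWindow("P2", 0.16, 0.21, ("FC1", "FCz", "FC2"))
    means = {}
    for gain in (1.0, 2.0):
        comps = EEGParams().erp_components
        scaled = tuple(
            type(c)(c.name, c.amplitude * gain, c.centre, c.spatial_sigma,
                    c.latency, c.width, c.window,
                    {k: v * gain for k, v in c.effects.items()})
            for c in comps
        )
        params = EEGParams(noise_sd=0.0, alpha_amp=0.0, erp_subject_sd=0.0,
                           ali_subject_sd=0.0, erp_components=scaled)
        ep = simulate_eeg_epochs(plan, params, 3, picks=list(window.electrodes))
        means[gain] = single_trial_amplitude(ep, window)["amplitude"].mean()
    assert means[2.0] == pytest.approx(2 * means[1.0], rel=1e-9)


def _amplitude_table(rng, n_subjects=6, effect=0.0):
    rows = []
    for s in range(n_subjects):
        intercept = rng.normal(0, 1)
        for snr in (0, -10):
            for load in (1, 2):
                for pred in ("predictable", "unpredictable"):
                    n = 20
                    y = intercept + rng.normal(0, 2, n)
                    if pred == "unpredictable":
                        y += effect
                    for v in y:
                        rows.append({"participant": s, "snr_db": snr,
                                     "memory_load": load, "predictability": pred,
                                     "amplitude": v})
    return pd.DataFrame(rows)


def test_lmm_recovers_injected_predictability_effect():
    rng = np.random.default_rng(3)
    table, fit = fit_component_lmm(_amplitude_table(rng, effect=0.8))
    pred = table[table["term"] == "predictability"].iloc[0]
    assert pred["estimate"] == pytest.approx(0.8, abs=0.25)
    assert pred["p"] < 0.01
    assert pred["r"] == pytest.approx(
        np.sqrt(pred["t"] ** 2 / (pred["t"] ** 2 + pred["df"])), abs=1e-9)
    assert fit.n_groups == 6


def test_lmm_requires_varying_factors_and_multiple_participants():
    rng = np.random.default_rng(4)
    table = _amplitude_table(rng)
    with pytest.raises(ValueError, match="participants"):
        fit_component_lmm(table[table["participant"] == 0])
    with pytest.raises(ValueError, match="vary"):
        fit_component_lmm(table[table["memory_load"] == 1])


def test_lmm_supports_subgroup_and_extra_factor_refits():
    rng = np.random.default_rng(5)
    table = _amplitude_table(rng)
    table["is_nback"] = np.tile([True, False], len(table) // 2)
    sub, _ = fit_component_lmm(table[table["memory_load"] == 1],
                               factors=("snr_db", "predictability"))
    assert set(sub["term"]) == {"intercept", "snr_db", "predictability",
                                "snr_db x predictability"}
    tgt, _ = fit_component_lmm(table,
                               factors=("snr_db", "memory_load", "predictability",
                                        "is_nback"),
                               interactions=False)
    assert "is_nback" in set(tgt["term"])
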