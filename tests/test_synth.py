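"""Synthetic generator: press model, noise spectrum, alpha injection, ground truth."""

import numpy as np
import pytest
from scipy import stats as sps

from predistract import build_experiment, simulate_responses
from predistract.preprocess import drop_block_initial_trials
from predistract.synth import (
    BehaviorParams,
    EEGParams,
    default_behavior_params,
    default_erp_components,
    ground_truth_report,
    simulate_eeg_epochs,
    _pink_noise,
)
from predistract.design import CONDITION_CELLS
from predistract import tfr


def _uniform_params(dprime, criterion):
    return BehaviorParams(dprime={c: dprime for c in CONDITION_CELLS},
                          criterion={c: criterion for c in CONDITION_CELLS})


def test_press_probability_symmetric_null(small_plan):
    p_hit, p_fa = _uniform_params(0.0, 0.0).press_probabilities(CONDITION_CELLS[0])
    assert p_hit == p_fa == 0.5


def test_press_probability_matches_normal_cdf(plan):
    params = _uniform_params(2.1232, 0.2200)     # hit rate 0.8, FA rate 0.1
    log = simulate_responses(plan, params, 99)
    merged = plan.to_frame().merge(log, on=["block", "trial"])
    hits = merged.loc[merged["is_nback"], "pressed"]
    fas = merged.loc[~merged["is_nback"], "pressed"]
    assert hits.mean() == pytest.approx(0.8, abs=3 * np.sqrt(0.16 / len(hits)))
    assert fas.mean() == pytest.approx(0.1, abs=3 * np.sqrt(0.09 / len(fas)))


def test_extreme_criterion_suppresses_presses(small_plan):
    log = simulate_responses(small_plan, _uniform_params(1.0, 20.0), 1)
    assert not log["pressed"].any()
    assert log["rt_s"].isna().all()


def test_reaction_times_within_response_window(small_plan):
    log = simulate_responses(small_plan, default_behavior_params(), 2)
    rts = log.loc[log["pressed"], "rt_s"]
    assert len(rts) > 0
    assert ((rts > 0) & (rts <= 2.0)).all()


def test_pink_noise_spectral_slope():
    rng = np.random.default_rng(0)
    x = _pink_noise(rng, (40, 2, 1000), 250.0, 1.0, 5.0)
    assert x.std() == pytest.approx(5.0, rel=0.05)
    f = np.fft.rfftfreq(1000, 1 / 250.0)
    psd = (np.abs(np.fft.rfft(x, axis=-1)) ** 2).mean(axis=(0, 1))
    band = (f >= 1) & (f <= 50)
    slope = np.polyfit(np.log(f[band]), np.log(psd[band]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.15)


@pytest.fixture(scope="module")
def alpha_only_epochs():
    plan = build_experiment(21, n_trials_per_block=10)
    params = EEGParams(noise_sd=0.0, erp_components=(), ali_subject_sd=0.0,
                       alpha_jitter_sigma=0.0)
    return simulate_eeg_epochs(plan, params, 5, picks=["PO3", "PO4", "Fp1", "FCz"])


def test_alpha_power_is_band_and_posterior_specific(alpha_only_epochs):
    ep = alpha_only_epochs
    f = np.fft.rfftfreq(ep.data.shape[-1], 1 / ep.sfreq)
    psd = (np.abs(np.fft.rfft(ep.data, axis=-1)) ** 2).mean(axis=0)
    alpha = psd[:, (f >= 8) & (f <= 12)].sum(axis=1)
    beta = psd[:, (f >= 15) & (f <= 30)].sum(axis=1)
    po3, po4, fp1, fcz = range(4)
    assert alpha[po3] > 100 * beta[po3]
    assert alpha[po4] > 100 * beta[po4]
    # the Gaussian scalp profile leaves only a small residue frontally
    assert alpha[fp1] < 0.05 * alpha[po3]


def test_zero_ali_gives_hemispherically_equal_power():
    plan = build_experiment(22, n_trials_per_block=10)
    params = EEGParams(noise_sd=0.0, erp_components=(), ali_subject_sd=0.0,
                       alpha_jitter_sigma=0.0,
                       ali_true=tuple(sorted({(w, p): 0.0
                                              for w in ("T1", "T2")
                                              for p in ("predictable", "unpredictable")
                                              }.items())))
    ep = simulate_eeg_epochs(plan, params, 6, picks=["PO3", "PO4"])
    power = (ep.data ** 2).mean(axis=(0, 2))
    assert power[0] == pytest.approx(power[1], rel=1e-6)


def test_closed_form_ali_oracle():
    """Noise-free single posterior pair: pipeline ALI equals the gain formula.

    With constant hemispheric gains over the whole analysis range, the
    Hanning-window FFT power of the two pure oscillators is exact at 10 Hz and
    ALI = (g_ipsi^2 - g_contra^2) / (g_ipsi^2 + g_contra^2) = a to numerical
    precision.
    """
    a = 0.2
    plan = build_experiment(23, n_trials_per_block=8)
    params = EEGParams(noise_sd=0.0, erp_components=(), ali_subject_sd=0.0,
                       alpha_jitter_sigma=0.0,
                       windows=(("T1", (-0.7, 0.7)),),
                       ali_true=((("T1", "predictable"), a),
                                 (("T1", "unpredictable"), a)))
    ep = simulate_eeg_epochs(plan, params, 7, picks=["PO3", "PO4"])
    foi = np.arange(8, 13.0)
    for side in ("left", "right"):
        kept = ep.select_trials(ep.metadata["attend_side"].to_numpy() == side)
        power = tfr.tfr_power(kept.data, kept.times, kept.sfreq, foi=foi,
                              precision="double").mean(axis=0)
        ali = tfr.compute_ali(power, ep.channels, side, roi_pairs=[("PO3", "PO4")],
                              foi=foi)
        # the residual is interference between the oscillator's positive- and
        # negative-frequency leakage through the finite Hanning taper; it
        # averages down with trials but never vanishes exactly
        assert np.max(np.abs(ali - a)) < 2e-5


def test_erp_components_scale_condition_averages():
    plan = build_experiment(24, n_trials_per_block=20)
    params = EEGParams(noise_sd=0.0, alpha_amp=0.0, ali_subject_sd=0.0,
                       erp_subject_sd=0.0)
    ep = simulate_eeg_epochs(plan, params, 8, picks=["FCz", "Pz"])
    meta = ep.metadata
    p2 = next(c for c in default_erp_components() if c.name == "P2")
    peak_idx = np.argmin(np.abs(ep.times - p2.latency))
    unpred = ep.data[(meta["predictability"] == "unpredictable").to_numpy()
                     & ~meta["is_nback"].to_numpy(), 0, peak_idx]
    pred = ep.data[(meta["predictability"] == "predictable").to_numpy()
                   & ~meta["is_nback"].to_numpy(), 0, peak_idx]
    # other components overlap at the peak sample, but the difference between
    # predictability levels isolates the injected P2 effect
    injected_delta = 0.4
    assert unpred.mean() - pred.mean() == pytest.approx(injected_delta, abs=0.02)


def test_zero_amplitude_components_leave_flat_poststimulus_average():
    plan = build_experiment(25, n_trials_per_block=10)
    comps = tuple(
        type(c)(c.name, 0.0, c.centre, c.spatial_sigma, c.latency, c.width, c.window, {})
        for c in default_erp_components()
    )
    params = EEGParams(noise_sd=0.0, alpha_amp=0.0, erp_components=comps,
                       ali_subject_sd=0.0, erp_subject_sd=0.0)
    ep = simulate_eeg_epochs(plan, params, 9, picks=["FCz"])
    assert np.allclose(ep.data, 0.0)


def test_determinism_and_seed_sensitivity(small_plan):
    params = EEGParams()
    a = simulate_eeg_epochs(small_plan, params, 42, picks=["PO3", "PO4"])
    b = simulate_eeg_epochs(small_plan, params, 42, picks=["PO3", "PO4"])
    c = simulate_eeg_epochs(small_plan, params, 43, picks=["PO3", "PO4"])
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)
    r1 = simulate_responses(small_plan, default_behavior_params(), 3)
    r2 = simulate_responses(small_plan, default_behavior_params(), 3)
    assert r1.equals(r2)


def test_ground_truth_report_roundtrip():
    behavior = default_behavior_params()
    eeg = EEGParams()
    report = ground_truth_report(behavior, eeg)
    d_rows = report[report["kind"] == "dprime"]
    for row in d_rows.itertuples():
        assert row.value == behavior.dprime[(row.snr_db, row.memory_load,
                                             row.predictability)]
    ali_rows = report[report["kind"] == "ali"]
    assert len(ali_rows) == 4
    for row in ali_rows.itertuples():
        assert row.value == eeg.ali_map[(row.name, row.predictability)]
    assert (report["kind"] == "erp_effect").sum() == \
        sum(len(c.effects) for c in eeg.erp_components)


def test_eeg_params_validation():
    with pytest.raises(ValueError):
        EEGParams(sampling_rate=15.0)
    with pytest.raises(ValueError):
        EEGParams(ali_true=((("T1", "predictable"), 1.5),
                            (("T1", "unpredictable"), 0.0),
                            (("T2", "predictable"), 0.0),
                            (("T2", "unpredictable"), 0.0)))
    with pytest.raises(ValueError):
        BehaviorParams(dprime={}, criterion={})
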