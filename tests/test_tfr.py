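"""Time-frequency power, AMI/ALI arithmetic and window selection."""

import numpy as np
import pandas as pd
import pytest

from predistract.stats import rm_anova
from predistract.tfr import (
    DEFAULT_FOI,
    DEFAULT_TOI,
    aggregate_powers,
    ali_window_anova,
    compute_ali,
    compute_ami,
    select_windows,
    tfr_power,
)


def _sinusoid(freq, amp=2.0, sfreq=250.0, n_trials=1, n_ch=1, phase=0.3):
    n = int(2 * sfreq)
    t = -1.0 + np.arange(n) / sfreq
    data = np.tile(amp * np.sin(2 * np.pi * freq * t + phase), (n_trials, n_ch, 1))
    return data, t


def test_pure_sinusoid_power_peaks_at_its_bin_and_is_stable():
    data, t = _sinusoid(10.0, amp=2.0)
    p = tfr_power(data, t, 250.0)
    spectrum = p[0, 0].mean(axis=1)
    assert DEFAULT_FOI[np.argmax(spectrum)] == 10.0
    # mean-square power of a 2-uV sinusoid is 2 uV^2, at every time point
    # (single-precision inner products: ~1e-4 relative accuracy)
    assert np.allclose(p[0, 0, 9, :], 2.0, rtol=1e-3)


def test_power_is_quadratic_in_amplitude():
    small, t = _sinusoid(10.0, amp=1.5)
    large, _ = _sinusoid(10.0, amp=3.0)
    p_small = tfr_power(small, t, 250.0)
    p_large = tfr_power(large, t, 250.0)
    assert np.allclose(p_large, 4 * p_small, rtol=1e-6, atol=1e-12)


def test_white_noise_spectrum_is_flat():
    rng = np.random.default_rng(0)
    data = rng.normal(0, 1.0, (200, 1, 500))
    t = -1.0 + np.arange(500) / 250.0
    p = tfr_power(data, t, 250.0).mean(axis=(0, 1, 3))
    band = p[4:46]
    assert band.max() / band.min() < 1.35      # flat within sampling noise


def test_out_of_bounds_window_raises():
    data, t = _sinusoid(10.0)
    with pytest.raises(ValueError, match="bounds"):
        tfr_power(data, t, 250.0, toi=np.array([0.9]))
    with pytest.raises(ValueError, match="Nyquist"):
        tfr_power(data, t, 250.0, foi=np.array([150.0]))


def test_ami_arithmetic_and_antisymmetry():
    left = np.array([[1.0, 2.0, 0.0, 1.0]])
    right = np.array([[3.0, 2.0, 0.0, 0.0]])
    ami = compute_ami(left, right)
    assert ami[0, 0] == pytest.approx(-0.5)
    assert ami[0, 1] == 0.0
    assert np.isnan(ami[0, 2])                 # undefined at zero power
    assert ami[0, 3] == 1.0
    assert np.allclose(compute_ami(right, left)[0, [0, 1, 3]],
                       -ami[0, [0, 1, 3]])
    with pytest.raises(ValueError):
        compute_ami(np.array([-1.0]), np.array([1.0]))


def _pair_power(p_left, p_right, n_time=5):
    """Power tensor for channels [PO3, PO4] constant over 5 freqs and time."""
    power = np.empty((2, 5, n_time))
    power[0] = p_left
    power[1] = p_right
    return power


def test_ali_arithmetic_and_side_symmetry():
    power = _pair_power(2.0, 1.0)
    foi = np.arange(8, 13.0)
    ali_l = compute_ali(power, ["PO3", "PO4"], "left", [("PO3", "PO4")], foi=foi)
    assert np.allclose(ali_l, 1 / 3)           # ipsi 2, contra 1
    ali_r = compute_ali(power, ["PO3", "PO4"], "right", [("PO3", "PO4")], foi=foi)
    assert np.allclose(ali_r, -1 / 3)          # ipsi/contra exchange flips sign
    mirrored = _pair_power(1.0, 2.0)
    assert np.allclose(
        compute_ali(mirrored, ["PO3", "PO4"], "right", [("PO3", "PO4")], foi=foi),
        ali_l)                                 # mirror-symmetric data, same ALI
    assert np.all(np.abs(ali_l) <= 1)
    with pytest.raises(ValueError):
        compute_ali(power, ["PO3", "PO4"], "up", [("PO3", "PO4")], foi=foi)
    with pytest.raises(ValueError, match="ROI"):
        compute_ali(power, ["PO3", "Oz"], "left", [("PO3", "PO4")], foi=foi)


def test_aggregate_powers_weighted_mean():
    powers = {("a", "x"): np.full((1, 1, 1), 1.0), ("b", "x"): np.full((1, 1, 1), 4.0)}
    counts = {("a", "x"): 1, ("b", "x"): 3}
    agg, totals = aggregate_powers(powers, counts, key_fn=lambda k: k[1])
    assert agg["x"][0, 0, 0] == pytest.approx((1 + 3 * 4) / 4)
    assert totals["x"] == 4


def test_select_windows_null_and_localised_effect():
    rng = np.random.default_rng(1)
    n_subj, n_t = 12, len(DEFAULT_TOI)
    null_left = rng.normal(0, 0.1, (n_subj, n_t))
    sel = select_windows(null_left, null_left + rng.normal(0, 0.1, (n_subj, n_t)))
    assert isinstance(sel.windows, list)
    effect = np.zeros(n_t)
    effect[(DEFAULT_TOI >= 0.3) & (DEFAULT_TOI <= 0.5)] = 1.0
    left = rng.normal(0, 0.05, (n_subj, n_t)) + effect
    right = rng.normal(0, 0.05, (n_subj, n_t)) - effect
    sel = select_windows(left, right)
    assert sel.covers(0.3, 0.5)
    assert not sel.covers(-0.7, 0.7)


def test_select_windows_zero_t_everywhere_selects_nothing():
    # paired differences alternate +/- across subjects: t = 0, p = 1 at each point
    base = np.zeros((4, 10))
    diff = np.array([1.0, -1.0, 1.0, -1.0])[:, None] * np.ones((4, 10))
    sel = select_windows(base + diff, base, times=np.linspace(-0.45, 0.45, 10))
    assert np.allclose(sel.pvalues, 1.0)
    assert sel.windows == []
    with pytest.raises(ValueError):
        select_windows(base[:1], base[:1], times=np.linspace(-0.45, 0.45, 10))


def _ali_frame(rng, interaction=0.0):
    rows = []
    for s in range(10):
        offset = rng.normal(0, 0.02)
        for snr in (0, -10):
            for load in (1, 2):
                for window in ("T1", "T2"):
                    for pred in ("predictable", "unpredictable"):
                        val = offset + rng.normal(0, 0.03)
                        if window == "T2":
                            val += 0.2
                        if window == "T1" and pred == "unpredictable":
                            val -= interaction
                        rows.append({"participant": s, "snr_db": snr,
                                     "memory_load": load, "window": window,
                                     "predictability": pred, "ali": val})
    return pd.DataFrame(rows)


def test_ali_window_anova_structure_and_interaction():
    rng = np.random.default_rng(2)
    main, follow = ali_window_anova(_ali_frame(rng, interaction=0.15))
    assert len(main) == 15                      # 4 factors: all mains + interactions
    wxp = main[main["effect"] == "window x predictability"].iloc[0]
    assert wxp["p"] < 0.05
    assert set(follow) == {"T1", "T2"}
    t1_pred = follow["T1"][follow["T1"]["effect"] == "predictability"].iloc[0]
    assert t1_pred["p"] < 0.05


def test_anova_factor_without_marginal_effect_gives_zero_f():
    """Per-subject predictability shifts that cancel leave its main F at zero."""
    rng = np.random.default_rng(3)
    frame = _ali_frame(rng)
    signs = np.where(frame["participant"] % 2 == 0, 1.0, -1.0)
    pred = np.where(frame["predictability"] == "unpredictable", 0.1, -0.1)
    frame["ali"] = frame["ali"] + signs * pred
    base = rm_anova(frame, "ali", "participant",
                    ["snr_db", "memory_load", "window", "predictability"])
    # remove the (tiny, sampling-driven) marginal difference exactly
    marg = frame.groupby("predictability", observed=True)["ali"].transform("mean")
    frame["ali"] = frame["ali"] - marg
    table = rm_anova(frame, "ali", "participant",
                     ["snr_db", "memory_load", "window", "predictability"])
    f = table.loc[table["effect"] == "predictability", "F"].iloc[0]
    assert f == pytest.approx(0, abs=1e-12)
    assert base.loc[base["effect"] == "predictability", "F"].iloc[0] >= f
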