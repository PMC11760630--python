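"""End-to-end orchestration: design -> synthesis -> preprocessing -> analyses.

One master seed drives everything through a numpy SeedSequence: per subject,
independent child sequences are spawned for the experiment plan, the button
presses and the EEG, so subjects can be generated in any order with identical
results. The pipeline emits the design, per-subject behaviour, the
signal-detection and ALI ANOVA tables, the single-trial ERP mixed-model
summaries, and a report pairing every injected ground-truth effect with its
recovered estimate.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import erp as erpmod
from . import preprocess as prep
from . import synth, tfr
from .design import build_experiment
from .montage import CHANNELS_64, ROI_LEFT, ROI_RIGHT

logger = logging.getLogger(__name__)

#: channels the ERP branch needs (candidate peak rows + mastoid reference)
ERP_CHANNELS = ["F1", "Fz", "F2", "FC1", "FCz", "FC2", "C1", "Cz", "C2",
                "TP9", "TP10"]


@dataclass
class PipelineConfig:
    """All analysis constants, with the study's values as defaults."""

    seed: int = 0
    n_subjects: int = 33
    trials_per_block: int = 120
    sampling_rate: float = 250.0
    nback_rate: float = 0.2
    high_pass_hz: float = 0.1
    low_pass_hz: float = 100.0
    amplitude_threshold_uv: float = 160.0
    baseline_s: tuple = (-0.2, 0.0)
    alpha_band_hz: tuple = (8.0, 12.0)
    tfr_window_s: float = 0.5
    ali_windows: dict = field(default_factory=lambda: {"T1": tfr.T1, "T2": tfr.T2})
    fdr_q: float = 0.05
    do_filter: bool = True
    channel_scope: str = "full"        # "full" or "reduced" (ERP + ROI channels only)
    out_dir: str = "predistract_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        cfg = cls(**raw)
        if isinstance(cfg.baseline_s, list):
            cfg.baseline_s = tuple(cfg.baseline_s)
        if isinstance(cfg.alpha_band_hz, list):
            cfg.alpha_band_hz = tuple(cfg.alpha_band_hz)
        cfg.ali_windows = {k: tuple(v) for k, v in cfg.ali_windows.items()}
        return cfg

    def channels(self) -> list[str]:
        if self.channel_scope == "full":
            return list(CHANNELS_64)
        seen = dict.fromkeys(ERP_CHANNELS + ROI_LEFT + ROI_RIGHT)
        return list(seen)


def subject_seeds(master_seed: int, n_subjects: int):
    """Independent (plan, presses, eeg) seed sequences per subject."""
    children = np.random.SeedSequence(master_seed).spawn(n_subjects)
    return [tuple(c.spawn(3)) for c in children]


def _preprocess(epochs, cfg: PipelineConfig):
    if cfg.do_filter:
        epochs = prep.bandpass_filter(epochs, cfg.high_pass_hz, cfg.low_pass_hz)
    epochs = prep.reject_amplitude(epochs, cfg.amplitude_threshold_uv)
    return prep.drop_block_initial_trials(epochs)


def run_pipeline(cfg: PipelineConfig, behavior_params: synth.BehaviorParams | None = None,
                 eeg_params: synth.EEGParams | None = None) -> dict:
    """Run the full simulated study and write all outputs to ``cfg.out_dir``."""
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    behavior_params = behavior_params or synth.default_behavior_params()
    eeg_params = eeg_params or synth.EEGParams(sampling_rate=cfg.sampling_rate)
    channels = cfg.channels()

    sdt_rows, ali_rows = [], []
    fn_amp_rows, p2_cache = [], []
    ga_sum, ga_n = None, 0
    ami_series = {"predictable": {"left": [], "right": []},
                  "unpredictable": {"left": [], "right": []}}
    roi_channels = list(dict.fromkeys(ROI_LEFT + ROI_RIGHT))

    for subj, (plan_seed, press_seed, eeg_seed) in enumerate(
            subject_seeds(cfg.seed, cfg.n_subjects)):
        stage_t = time.time()
        plan = build_experiment(plan_seed, cfg.trials_per_block, cfg.nback_rate)
        if subj == 0:
            (out / "plan.json").write_text(plan.to_json())
            plan.to_frame().to_csv(out / "trials.tsv", sep="\t", index=False)

        presses = synth.simulate_responses(plan, behavior_params, press_seed)
        trials = prep.drop_block_initial_trials(plan.to_frame())
        counts = bhv.score_presses(trials, presses)
        sdt_rows.append(bhv.sdt_table(counts, participant=subj))

        epochs = synth.simulate_eeg_epochs(plan, eeg_params, eeg_seed, picks=channels)
        epochs = _preprocess(epochs, cfg)

        # --- ERP branch: mastoid reference, baseline correction -------------
        erp_epochs = prep.baseline_correct(
            prep.rereference(epochs.pick([c for c in ERP_CHANNELS if c in channels]),
                             "mastoids"),
            cfg.baseline_s)
        ga = erpmod.grand_average(erp_epochs)
        ga_sum = ga if ga_sum is None else ga_sum + ga
        ga_n += 1
        fn_tab = erpmod.single_trial_amplitude(erp_epochs, erpmod.fn_component_window())
        fn_tab["participant"] = subj
        fn_amp_rows.append(fn_tab)
        crop = erp_epochs.time_mask(0.05, 0.35)
        p2_cache.append((erp_epochs.data[:, :, crop], erp_epochs.metadata.copy()))
        p2_channels, p2_times = list(erp_epochs.channels), erp_epochs.times[crop]

        # --- alpha branch: common average reference --------------------------
        alpha_epochs = prep.rereference(epochs, "average")
        powers, pow_chs, pow_counts = tfr.condition_power(
            alpha_epochs, picks=[c for c in roi_channels if c in channels],
            window=cfg.tfr_window_s)
        ali_rows.append(tfr.subject_ali_table(powers, pow_chs, participant=subj,
                                              windows=cfg.ali_windows))
        by_pred_side, _ = tfr.aggregate_powers(powers, pow_counts,
                                               key_fn=lambda k: (k[2], k[3]))
        for pred in ("predictable", "unpredictable"):
            sides = {side: by_pred_side[(pred, side)] for side in ("left", "right")}
            l_series, r_series = tfr.roi_ami_series(sides, pow_chs,
                                                    band=cfg.alpha_band_hz)
            ami_series[pred]["left"].append(l_series)
            ami_series[pred]["right"].append(r_series)
        logger.info("subject %d done in %.1f s", subj, time.time() - stage_t)

    # ------------------------------------------------------------------ tables
    sdt_table = pd.concat(sdt_rows, ignore_index=True)
    sdt_table.to_csv(out / "sdt.tsv", sep="\t", index=False)
    results: dict = {"config": {**asdict(cfg),
                                "ali_windows": {k: list(v) for k, v in cfg.ali_windows.items()},
                                "baseline_s": list(cfg.baseline_s),
                                "alpha_band_hz": list(cfg.alpha_band_hz)}}

    if cfg.n_subjects >= 2:
        anovas = {dv: bhv.behavior_anova(sdt_table, dv)
                  for dv in ("hit_rate", "dprime", "criterion")}
        pd.concat([t.assign(dv=dv) for dv, t in anovas.items()]) \
            .to_csv(out / "behavior_anova.tsv", sep="\t", index=False)
        post = bhv.criterion_posthoc(sdt_table)
        results["behavior"] = {
            "anova": {dv: t.to_dict("records") for dv, t in anovas.items()},
            "criterion_posthoc": asdict(post),
        }

    # ERP: P2 window from the across-subject grand average, then the LMMs
    ga_mean = ga_sum / ga_n
    p2_window = erpmod.find_component_window(ga_mean, p2_channels, p2_times)
    p2_rows = []
    for subj, (data, meta) in enumerate(p2_cache):
        kept = meta["retained"].to_numpy(bool)
        idx = [p2_channels.index(ch) for ch in p2_window.electrodes]
        tmask = (p2_times >= p2_window.t_start - 1e-9) & (p2_times <= p2_window.t_end + 1e-9)
        tab = meta.loc[kept].copy()
        tab["amplitude"] = data[kept][:, idx, :][:, :, tmask].mean(axis=(1, 2))
        tab["participant"] = subj
        p2_rows.append(tab)
    p2_amp = pd.concat(p2_rows, ignore_index=True)
    fn_amp = pd.concat(fn_amp_rows, ignore_index=True)
    p2_amp.to_csv(out / "p2_amplitudes.tsv", sep="\t", index=False)
    fn_amp.to_csv(out / "fn_amplitudes.tsv", sep="\t", index=False)

    results["erp"] = {"p2_window": asdict(p2_window)}
    if cfg.n_subjects >= 2:
        p2_lmm, _ = erpmod.fit_component_lmm(p2_amp)
        fn_lmm, _ = erpmod.fit_component_lmm(fn_amp)
        target_lmm, _ = erpmod.fit_component_lmm(
            p2_amp, factors=("snr_db", "memory_load", "predictability", "is_nback"),
            interactions=False)
        fn_by_load = {
            int(load): erpmod.fit_component_lmm(
                fn_amp[fn_amp["memory_load"] == load],
                factors=("snr_db", "predictability"))[0].to_dict("records")
            for load in (1, 2)
        }
        results["erp"].update({
            "p2_lmm": p2_lmm.to_dict("records"),
            "fn_lmm": fn_lmm.to_dict("records"),
            "p2_target_contrast": target_lmm.to_dict("records"),
            "fn_by_load": fn_by_load,
        })
        with open(out / "erp_lmm.json", "w") as f:
            json.dump({k: v for k, v in results["erp"].items() if k != "p2_window"},
                      f, indent=1)

    # alpha: window selection and the 2x2x2x2 ANOVA
    ali_table = pd.concat(ali_rows, ignore_index=True)
    ali_table.to_csv(out / "ali.tsv", sep="\t", index=False)
    if cfg.n_subjects >= 2:
        selections = {}
        for pred in ("predictable", "unpredictable"):
            sel = tfr.select_windows(np.vstack(ami_series[pred]["left"]),
                                     np.vstack(ami_series[pred]["right"]),
                                     alpha=cfg.fdr_q)
            selections[pred] = sel.windows
        main, follow = tfr.ali_window_anova(ali_table)
        main.to_csv(out / "ali_anova.tsv", sep="\t", index=False)
        results["alpha"] = {
            "selected_windows": selections,
            "anova": main.to_dict("records"),
            "anova_by_window": {k: v.to_dict("records") for k, v in follow.items()},
        }

    results["recovery"] = _recovery_report(behavior_params, eeg_params, sdt_table,
                                           ali_table, results, cfg)
    results["runtime_s"] = round(time.time() - t_start, 2)
    with open(out / "report.json", "w") as f:
        json.dump(results, f, indent=1, default=_jsonify)
    return results


def _recovery_report(behavior_params, eeg_params, sdt_table, ali_table,
                     results, cfg) -> list[dict]:
    """Injected ground truth next to the recovered estimate, one row each."""
    rows = []
    cell_means = sdt_table.groupby(["snr_db", "memory_load", "predictability"],
                                   observed=True)[["dprime", "criterion"]].mean()
    for cell, sub in cell_means.iterrows():
        rows.append({"quantity": "dprime", "condition": list(cell),
                     "injected": behavior_params.dprime[cell],
                     "recovered": float(sub["dprime"])})
        rows.append({"quantity": "criterion", "condition": list(cell),
                     "injected": behavior_params.criterion[cell],
                     "recovered": float(sub["criterion"])})
    ali_means = ali_table.groupby(["window", "predictability"], observed=True)["ali"].mean()
    for (window, pred), value in ali_means.items():
        rows.append({"quantity": "ali", "condition": [window, pred],
                     "injected": eeg_params.ali_map[(window, pred)],
                     "recovered": float(value)})
    erp_effects = {
        ("p2_lmm", "snr_db"): ("P2", "snr_db==0"),
        ("p2_lmm", "memory_load"): ("P2", "memory_load==2"),
        ("p2_lmm", "predictability"): ("P2", "predictability==unpredictable"),
        ("fn_lmm", "snr_db"): ("frontal_negativity", "snr_db==0"),
        ("fn_lmm", "memory_load"): ("frontal_negativity", "memory_load==1"),
    }
    components = {c.name: c for c in eeg_params.erp_components}
    for (model, term), (comp, effect) in erp_effects.items():
        if model not in results.get("erp", {}):
            continue
        entry = next(r for r in results["erp"][model] if r["term"] == term)
        injected = components[comp].effects[effect]
        # coefficients contrast the +0.5-coded level; flip where the injected
        # delta is attached to the -0.5-coded level (memory_load==1)
        sign = -1.0 if effect == "memory_load==1" else 1.0
        rows.append({"quantity": f"{comp}:{term}", "condition": [],
                     "injected": injected,
                     "recovered": sign * float(entry["estimate"])})
    return rows


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
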