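"""Signal-detection analysis of n-back button presses.

A hit is a press on a trial whose target repeats the target n positions back;
a false alarm is a press on any other (scoreable) trial. Extreme rates of 0 or
1 are replaced by 1/(2N) and 1 - 1/(2N), with N the relevant trial count, before
computing sensitivity d' = z(H) - z(FA) and criterion c = -(z(H) + z(FA))/2
(positive c = conservative responding, i.e. a tendency to withhold presses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import stats as st

CONDITION_COLS = ["snr_db", "memory_load", "predictability"]


@dataclass(frozen=True)
class SDTCounts:
    n_targets: int
    n_nontargets: int
    hits: int
    false_alarms: int

    def __post_init__(self):
        if not (0 <= self.hits <= self.n_targets):
            raise ValueError("hits must lie in [0, n_targets]")
        if not (0 <= self.false_alarms <= self.n_nontargets):
            raise ValueError("false_alarms must lie in [0, n_nontargets]")


@dataclass(frozen=True)
class SDTResult:
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float


def correct_extreme_rate(count: int, n: int) -> float:
    """Proportion with the extreme-rate correction applied.

    0/n maps to 1/(2n) and n/n to 1 - 1/(2n); anything in between is count/n.
    """
    if n <= 0:
        raise ValueError("trial count must be positive")
    if count == 0:
        return 1.0 / (2 * n)
    if count == n:
        return 1.0 - 1.0 / (2 * n)
    return count / n


def sdt_metrics(counts: SDTCounts) -> SDTResult:
    h = correct_extreme_rate(counts.hits, counts.n_targets)
    fa = correct_extreme_rate(counts.false_alarms, counts.n_nontargets)
    zh, zfa = norm.ppf(h), norm.ppf(fa)
    return SDTResult(hit_rate=h, fa_rate=fa, dprime=float(zh - zfa),
                     criterion=float(-(zh + zfa) / 2))


def score_presses(trials: pd.DataFrame, presses: pd.DataFrame,
                  response_window_s: float = 2.0) -> dict[tuple, SDTCounts]:
    """Tally hits and false alarms per condition cell.

    ``trials`` is a plan trial table with block-initial (unscoreable) trials
    already dropped; ``presses`` has columns block, trial, pressed and rt_s.
    Presses on trials absent from ``trials`` (e.g. block-initial ones) are
    ignored with a warning. The two blocks of a condition are pooled.
    """
    merged = trials.merge(presses, on=["block", "trial"], how="left", indicator=False)
    merged["pressed"] = merged["pressed"].fillna(False).astype(bool)
    in_window = merged["pressed"] & (merged["rt_s"].fillna(0) <= response_window_s)
    merged["scored_press"] = in_window

    orphan = presses.merge(trials[["block", "trial"]], on=["block", "trial"],
                           how="left", indicator=True)
    n_orphan = int((orphan["_merge"].eq("left_only") & orphan["pressed"]).sum())
    if n_orphan:
        warnings.warn(f"ignoring {n_orphan} press(es) on excluded trials", stacklevel=2)

    out: dict[tuple, SDTCounts] = {}
    for cell, g in merged.groupby(CONDITION_COLS, observed=True):
        tgt = g[g["is_nback"]]
        non = g[~g["is_nback"]]
        out[cell] = SDTCounts(
            n_targets=len(tgt), n_nontargets=len(non),
            hits=int(tgt["scored_press"].sum()),
            false_alarms=int(non["scored_press"].sum()),
        )
    return out


def sdt_table(counts_by_cell: dict[tuple, SDTCounts], participant=0) -> pd.DataFrame:
    """Flatten per-cell SDT metrics into one row per condition."""
    rows = []
    for cell, counts in counts_by_cell.items():
        res = sdt_metrics(counts)
        rows.append({
            "participant": participant,
            **dict(zip(CONDITION_COLS, cell)),
            "n_targets": counts.n_targets, "n_nontargets": counts.n_nontargets,
            "hits": counts.hits, "false_alarms": counts.false_alarms,
            "hit_rate": res.hit_rate, "fa_rate": res.fa_rate,
            "dprime": res.dprime, "criterion": res.criterion,
        })
    return pd.DataFrame(rows)


def behavior_anova(table: pd.DataFrame, dv: str = "dprime") -> pd.DataFrame:
    """2 (SNR) x 2 (load) x 2 (predictability) repeated-measures ANOVA."""
    return st.rm_anova(table, dv=dv, subject="participant", within=CONDITION_COLS)


def criterion_posthoc(table: pd.DataFrame, snr_db: int = 0,
                      memory_load: int = 1) -> st.TTestResult:
    """Paired t on criterion: predictable vs unpredictable within one load cell.

    Defaults to the easiest cell (0 dB SNR, 1-back), where the original study
    reported a less conservative bias for predictable distractors.
    """
    cell = table[(table["snr_db"] == snr_db) & (table["memory_load"] == memory_load)]
    wide = cell.pivot(index="participant", columns="predictability", values="criterion")
    return st.paired_t(wide["predictable"].to_numpy(), wide["unpredictable"].to_numpy())
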