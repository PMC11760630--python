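"""Shared inferential machinery.

Repeated-measures ANOVA with partial eta-squared, paired t-tests with Cohen's
d, Benjamini-Hochberg FDR, and the standardised partial effect size
r = sqrt(t^2 / (t^2 + df)) used for mixed-model coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t-test; Cohen's d = |t| / sqrt(n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length vectors of length >= 2")
    d = x - y
    if np.allclose(d, 0):
        return TTestResult(t=0.0, df=len(x) - 1, p=1.0, cohens_d=0.0)
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero variance of paired differences")
    res = sps.ttest_rel(x, y)
    n = len(x)
    t = float(res.statistic)
    return TTestResult(t=t, df=n - 1, p=float(res.pvalue), cohens_d=abs(t) / np.sqrt(n))


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def effect_size_r(t, df) -> float:
    """Standardised partial effect size r = sqrt(t^2 / (t^2 + df))."""
    df = float(df)
    if df <= 0:
        raise ValueError("df must be positive")
    t = float(t)
    return float(np.sqrt(t * t / (t * t + df)))


def partial_eta_squared(f, df_num, df_den) -> float:
    return float(f * df_num / (f * df_num + df_den))


def rm_anova(data: pd.DataFrame, dv: str, subject: str, within: list[str]) -> pd.DataFrame:
    """Fully-crossed within-subject ANOVA.

    Each effect is tested against its own subject-by-effect interaction (the
    standard univariate repeated-measures decomposition, computed via
    statsmodels AnovaRM). Returns one row per effect with columns
    ``effect, F, df_num, df_den, p, partial_eta_sq``. Cells with several
    observations per subject are averaged first. All within factors here are
    two-level, so sphericity holds trivially and no correction is applied.
    """
    cells = data.groupby([subject] + list(within), observed=True)[dv].mean().reset_index()
    counts = cells.groupby(subject, observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("design is unbalanced: unequal cell counts per subject")
    fit = AnovaRM(cells, depvar=dv, subject=subject, within=list(within)).fit()
    tab = fit.anova_table
    out = pd.DataFrame({
        "effect": [e.replace(":", " x ") for e in tab.index],
        "F": tab["F Value"].to_numpy(float),
        "df_num": tab["Num DF"].to_numpy(float),
        "df_den": tab["Den DF"].to_numpy(float),
        "p": tab["Pr > F"].to_numpy(float),
    })
    out["partial_eta_sq"] = [
        partial_eta_squared(f, dn, dd)
        for f, dn, dd in zip(out["F"], out["df_num"], out["df_den"])
    ]
    return out
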