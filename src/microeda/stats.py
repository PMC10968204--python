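"""Screening statistics: KS normality, Fisher's ratio, Spearman correlation,
and the per-feature / correlation summary tables.

Fisher's ratio here is the class-separability score
``(mean_high - mean_low)^2 / (var_high + var_low)`` with unbiased (n-1)
variances. The KS test uses moments estimated from the sample (no
Lilliefors correction) because it only gates the Spearman-vs-Pearson
choice, not formal inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float | None = None
    n: int | tuple = 0
    method: str = ""
    extra: dict = field(default_factory=dict)


def ks_normality(x) -> StatResult:
    """One-sample KS statistic of x against N(mean(x), sd(x))."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("KS normality undefined for a constant series")
    d, p = ss.kstest(x, "norm", args=(x.mean(), sd))
    return StatResult(statistic=float(d), p_value=float(p), n=x.size,
                      method="ks_normality(estimated moments, approximate p)")


def fishers_ratio(x_high, x_low) -> float:
    """(mean_h - mean_l)^2 / (var_h + var_l), unbiased variances."""
    a = np.asarray(x_high, dtype=float)
    b = np.asarray(x_low, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    denom = a.var(ddof=1) + b.var(ddof=1)
    if denom == 0:
        raise ValueError("both group variances are zero")
    return float((a.mean() - b.mean()) ** 2 / denom)


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for a constant series")
    rho = ss.spearmanr(x, y).statistic
    return float(rho)


def feature_class_summary(per_window: pd.DataFrame,
                          features: list[str] | None = None,
                          label_col: str = "label",
                          subject_col: str = "subject") -> pd.DataFrame:
    """Per-feature class summary: pooled mean ± SD in high/low-stress
    windows plus the mean and max of per-subject Fisher's ratios.

    Returns a features × statistics table (the low/high comparison grid);
    empty with a warning-shaped result if no labeled rows exist.
    """
    from microeda.features import EDA_FEATURES

    features = features or [f for f in EDA_FEATURES if f in per_window.columns]
    hi = per_window[per_window[label_col] == "high"]
    lo = per_window[per_window[label_col] == "low"]
    rows = {}
    for feat in features:
        if hi.empty or lo.empty:
            rows[feat] = {"mean_high": np.nan, "std_high": np.nan,
                          "mean_low": np.nan, "std_low": np.nan,
                          "fisher_mean": np.nan, "fisher_max": np.nan}
            continue
        ratios = []
        for _, grp in per_window.groupby(subject_col):
            h = grp.loc[grp[label_col] == "high", feat].to_numpy()
            l = grp.loc[grp[label_col] == "low", feat].to_numpy()
            if h.size >= 2 and l.size >= 2:
                try:
                    ratios.append(fishers_ratio(h, l))
                except ValueError:
                    pass
        if not ratios:  # single-subject fallback: pooled ratio
            try:
                ratios = [fishers_ratio(hi[feat], lo[feat])]
            except ValueError:
                ratios = [np.nan]
        rows[feat] = {
            "mean_high": hi[feat].mean(), "std_high": hi[feat].std(ddof=1),
            "mean_low": lo[feat].mean(), "std_low": lo[feat].std(ddof=1),
            "fisher_mean": float(np.mean(ratios)),
            "fisher_max": float(np.max(ratios)),
        }
    return pd.DataFrame(rows).T[["fisher_mean", "fisher_max", "mean_high",
                                 "std_high", "mean_low", "std_low"]]


def correlation_matrix(table: pd.DataFrame, rows: list[str],
                       cols: list[str] | None = None) -> pd.DataFrame:
    """Spearman correlation matrix between two variable sets.

    With ``cols=None`` the matrix is square and symmetric with a unit
    diagonal. Row/column order follows the declared variable order.
    """
    cols = cols if cols is not None else rows
    out = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for r in rows:
        for c in cols:
            if r == c:
                out.loc[r, c] = 1.0
                continue
            x = table[r].to_numpy(dtype=float)
            y = table[c].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            try:
                out.loc[r, c] = spearman(x[ok], y[ok])
            except ValueError:
                out.loc[r, c] = np.nan
    return out
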