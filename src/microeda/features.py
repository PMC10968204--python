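"""Time-domain EDA features, windowing, and environment synchronization.

SCL is the mean of the tonic component over 2-min windows; NSSCR counts
non-specific skin conductance responses per minute as prominence-qualified
local maxima of the phasic component; dphEDA is the time derivative of the
phasic component. ``sync_features`` joins 2 Hz EDA feature rows with the
1 Hz environment log, and ``build_feature_table`` assembles the per-sample
and per-window tables the statistics and modeling stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sg

from microeda.ingest import ENV_COLUMNS
from microeda.spectral import SpectralConfig, edasymp, mtvsymp, tvsymp

#: the six EDA indices, in the order the summary tables print them
EDA_FEATURES = ["MTVSymp", "TVSymp", "dphEDA", "NSSCR", "EDASymp", "SCL"]


@dataclass
class FeatureTable:
    """Per-timestamp (2 Hz) and per-window feature rows for ≥1 subjects.

    ``per_sample`` columns: subject, t, window, tonic, phasic, dphEDA,
    TVSymp, MTVSymp + environment columns. ``per_window`` columns: subject,
    window, the six EDA indices, environment window means, label columns.
    """

    per_sample: pd.DataFrame
    per_window: pd.DataFrame

    def subjects(self) -> list:
        return sorted(self.per_window["subject"].unique().tolist())


def scl(tonic, rate: float, window_s: float = 120.0) -> np.ndarray:
    """Mean of the tonic component over contiguous ``window_s`` windows."""
    x = np.asarray(tonic, dtype=float)
    w = int(round(window_s * rate))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if w > x.size:
        raise ValueError("window longer than signal")
    k = x.size // w
    return x[: k * w].reshape(k, w).mean(axis=1)


def detect_scrs(phasic, rate: float, min_amplitude: float = 0.01,
                min_distance_s: float = 1.0) -> np.ndarray:
    """Indices of SCR peaks: local maxima of the phasic component with
    prominence >= ``min_amplitude`` μS, at least ``min_distance_s`` apart."""
    x = np.asarray(phasic, dtype=float)
    idx, _ = sg.find_peaks(x, prominence=min_amplitude,
                           distance=max(int(round(min_distance_s * rate)), 1))
    return idx


def nsscr(phasic, rate: float, window_s: float = 60.0,
          min_amplitude: float = 0.01, min_distance_s: float = 1.0) -> np.ndarray:
    """Skin conductance responses per minute, per contiguous window."""
    if rate < 2:
        raise ValueError("NSSCR requires rate >= 2 Hz")
    x = np.asarray(phasic, dtype=float)
    w = int(round(window_s * rate))
    if w > x.size:
        raise ValueError("window longer than signal")
    peaks = detect_scrs(x, rate, min_amplitude, min_distance_s)
    k = x.size // w
    counts = np.histogram(peaks, bins=np.arange(k + 1) * w)[0]
    return counts / (window_s / 60.0)


def dpheda(phasic, rate: float) -> np.ndarray:
    """Derivative of the phasic component (μS/s), central differences with
    one-sided edges; length preserved."""
    x = np.asarray(phasic, dtype=float)
    return np.gradient(x, 1.0 / rate)


def sync_features(eda_df: pd.DataFrame, env_df: pd.DataFrame,
                  max_gap_s: float = 2.0) -> pd.DataFrame:
    """Join 2 Hz EDA feature rows with the 1 Hz environment log.

    Environment values are carried forward onto the EDA timestamps (gaps
    larger than ``max_gap_s`` leave NaN); EDA rows outside the overlapping
    time range are dropped, rows inside are all kept.
    """
    if "t" not in eda_df.columns or "t" not in env_df.columns:
        raise ValueError("both frames need a 't' column in seconds")
    lo = max(eda_df["t"].min(), env_df["t"].min())
    hi = min(eda_df["t"].max(), env_df["t"].max())
    if lo > hi:
        raise ValueError("EDA and environment time ranges do not overlap")
    eda = eda_df[(eda_df["t"] >= lo) & (eda_df["t"] <= hi)].sort_values("t")
    env = env_df.sort_values("t")
    return pd.merge_asof(eda, env, on="t", direction="backward",
                         tolerance=max_gap_s)


def build_feature_table(
    tonic2: np.ndarray,
    phasic2: np.ndarray,
    env_df: pd.DataFrame,
    *,
    rate: float = 2.0,
    subject: str = "S0",
    window_s: float = 900.0,
    scl_window_s: float = 120.0,
    nsscr_min_amplitude: float = 0.01,
    spectral_cfg: SpectralConfig | None = None,
    labels: pd.DataFrame | None = None,
) -> FeatureTable:
    """Assemble per-sample and per-window feature tables for one subject.

    ``tonic2``/``phasic2`` are the decomposition components resampled to
    2 Hz; ``env_df`` is the 1 Hz environment log; ``labels`` (optional) has
    columns ``window`` and any label/report columns to join per window.
    Per-window NSSCR/SCL/EDASymp/TVSymp/MTVSymp use the experiment windows
    (default 15 min); 2-min SCL sub-windows are also reported separately.
    """
    cfg = spectral_cfg or SpectralConfig(analysis_rate=rate)
    tonic2 = np.asarray(tonic2, dtype=float)
    phasic2 = np.asarray(phasic2, dtype=float)
    n = tonic2.size
    t = np.arange(n) / rate
    eda2 = tonic2 + phasic2

    # detrended series for spectral indices
    from microeda.ingest import EDASignal, butter_highpass

    detrended = butter_highpass(EDASignal(values=eda2, rate=rate))
    tvs = tvsymp(detrended, cfg)
    mtv = mtvsymp(tvs, rate, cfg.mtvsymp_lookback)

    per_sample = pd.DataFrame({
        "subject": subject,
        "t": t,
        "window": (t // window_s).astype(int),
        "tonic": tonic2,
        "phasic": phasic2,
        "dphEDA": dpheda(phasic2, rate),
        "TVSymp": tvs,
        "MTVSymp": mtv,
    })
    per_sample = sync_features(per_sample, env_df)

    rows = []
    n_windows = int(np.floor(n / (window_s * rate)))
    if n_windows == 0:
        raise ValueError(
            f"signal ({n / rate:.0f}s) shorter than one {window_s:.0f}s window"
        )
    w_samples = int(round(window_s * rate))
    for w in range(n_windows):
        sl = slice(w * w_samples, (w + 1) * w_samples)
        seg = detrended.evolve(detrended.values[sl], f"window{w}")
        row = {
            "subject": subject,
            "window": w,
            "SCL": float(np.mean(tonic2[sl])),
            "NSSCR": float(np.mean(nsscr(phasic2[sl], rate, 60.0,
                                         nsscr_min_amplitude))),
            "dphEDA": float(np.mean(dpheda(phasic2[sl], rate))),
            "TVSymp": float(np.mean(tvs[sl])),
            "MTVSymp": float(np.mean(mtv[sl])),
            "EDASymp": edasymp(seg, cfg)["normalized"],
            "EDASymp_power": edasymp(seg, cfg)["power"],
        }
        env_w = per_sample[per_sample["window"] == w]
        for c in ENV_COLUMNS:
            if c in env_w.columns:
                row[c] = float(env_w[c].mean())
        rows.append(row)
    per_window = pd.DataFrame(rows)
    if labels is not None:
        per_window = per_window.merge(labels, on="window", how="left")

    return FeatureTable(per_sample=per_sample, per_window=per_window)


def scl_subwindows(tonic2: np.ndarray, rate: float = 2.0,
                   window_s: float = 120.0) -> pd.DataFrame:
    """2-min SCL series as a DataFrame (window start time, SCL)."""
    vals = scl(tonic2, rate, window_s)
    return pd.DataFrame({"t_start": np.arange(vals.size) * window_s, "SCL": vals})
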