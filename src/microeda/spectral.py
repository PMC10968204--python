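"""Frequency-domain sympathetic indices from 2 Hz EDA.

Three indices are computed from the detrended 2 Hz conductance signal:

* **EDASymp** — normalized spectral power in 0.045–0.25 Hz, from a Welch
  estimate with 128-point Blackman segments.
* **TVSymp** — mean time-varying spectral amplitude in 0.08–0.24 Hz,
  obtained by variable frequency complex demodulation (VFCDM): the signal
  is demodulated at a grid of center frequencies, each component extracted
  with a zero-phase low-pass, refined by re-demodulating around the
  component's own instantaneous frequency, and the in-band components are
  summed; TVSymp is the analytic amplitude of that sum.
* **MTVSymp** — TVSymp minus its own mean over the preceding 5 s window,
  clipped at zero, emphasizing abrupt sympathetic surges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sg


@dataclass(frozen=True)
class SpectralConfig:
    analysis_rate: float = 2.0  # Hz
    edasymp_band: tuple[float, float] = (0.045, 0.25)
    tvsymp_band: tuple[float, float] = (0.08, 0.24)
    fft_window_length: int = 128  # samples
    window_kind: str = "blackman"
    segment_overlap: str = "half"  # "half" (50%) or "literal" (0.5 s = 1 sample)
    mtvsymp_lookback: float = 5.0  # s
    vfcdm_spacing: float = 0.03  # Hz, center-frequency grid step
    vfcdm_bandwidth: float = 0.03  # Hz, demodulation bandwidth
    vfcdm_lpf_order: int = 6

    def __post_init__(self) -> None:
        nyq = self.analysis_rate / 2.0
        for lo, hi in (self.edasymp_band, self.tvsymp_band):
            if not 0 < lo < hi < nyq:
                raise ValueError("bands must lie within (0, Nyquist)")
        if self.fft_window_length < 8:
            raise ValueError("fft_window_length must be >= 8")


def _check_rate(sig, cfg: SpectralConfig) -> np.ndarray:
    if not np.isclose(sig.rate, cfg.analysis_rate):
        raise ValueError(
            f"expected {cfg.analysis_rate} Hz input, got {sig.rate} Hz; resample first"
        )
    return np.asarray(sig.values, dtype=float)


def edasymp(sig, cfg: SpectralConfig | None = None) -> dict:
    """Sympathetic spectral power in the 0.045–0.25 Hz band.

    Returns ``{"power": band power (input units², Welch spectrum),
    "normalized": band power / total power above DC}``.
    """
    cfg = cfg or SpectralConfig()
    x = _check_rate(sig, cfg)
    L = cfg.fft_window_length
    if x.size < L:
        raise ValueError(f"signal shorter than one {L}-sample window")
    noverlap = L // 2 if cfg.segment_overlap == "half" else 1
    f, p = sg.welch(x, fs=cfg.analysis_rate, window=cfg.window_kind,
                    nperseg=L, noverlap=noverlap, detrend=False,
                    scaling="spectrum")
    lo, hi = cfg.edasymp_band
    in_band = (f >= lo) & (f <= hi)
    above_dc = f > 0
    total = p[above_dc].sum()
    band = p[in_band].sum()
    return {"power": float(band), "normalized": float(band / total) if total > 0 else 0.0}


def _vfcdm_components(x: np.ndarray, fs: float, cfg: SpectralConfig):
    """First-stage fixed-band CDM components and their carrier grid."""
    n = x.size
    t = np.arange(n) / fs
    centers = np.arange(cfg.vfcdm_spacing, fs / 2, cfg.vfcdm_spacing)
    sos = sg.butter(cfg.vfcdm_lpf_order, cfg.vfcdm_bandwidth / 2.0,
                    btype="lowpass", fs=fs, output="sos")
    padlen = min(3 * (2 * len(sos) + 1), max(n - 2, 0))
    comps = []
    for fk in centers:
        carrier = np.exp(-2j * np.pi * fk * t)
        z = sg.sosfiltfilt(sos, x * carrier, padlen=padlen)
        comps.append(2.0 * np.real(z * np.conj(carrier)))
    return np.array(comps), centers, sos, padlen


def _refine_component(c: np.ndarray, fk: float, fs: float, sos, padlen) -> np.ndarray:
    """Second VFCDM stage: re-demodulate a component at its own
    instantaneous frequency (smoothed), recovering a cleaner narrow-band
    component. Near-zero components are returned unchanged."""
    if np.sqrt(np.mean(c ** 2)) < 1e-12:
        return c
    analytic = sg.hilbert(c)
    phase = np.unwrap(np.angle(analytic))
    inst_f = np.gradient(phase) * fs / (2 * np.pi)
    # smooth IF over ~4 s and keep it physical
    width = max(int(round(4 * fs)), 1)
    kernel = np.ones(width) / width
    inst_f = np.convolve(inst_f, kernel, mode="same")
    inst_f = np.clip(inst_f, 0.0, fs / 2)
    psi = 2 * np.pi * np.cumsum(inst_f) / fs
    w = sg.sosfiltfilt(sos, c * np.exp(-1j * psi), padlen=padlen)
    return 2.0 * np.real(w * np.exp(1j * psi))


def tvsymp(sig, cfg: SpectralConfig | None = None, *, normalize: bool = False,
           refine: bool = True) -> np.ndarray:
    """Time-varying sympathetic amplitude series (0.08–0.24 Hz content).

    With ``normalize=True`` the in-band reconstruction is scaled to unit
    variance before amplitude extraction (the convention used when TVSymp
    values are compared across subjects); the default returns amplitudes in
    the input's units.
    """
    cfg = cfg or SpectralConfig()
    x = _check_rate(sig, cfg)
    if x.size < 60 * cfg.analysis_rate:
        raise ValueError("TVSymp needs at least 60 s of signal")
    if np.allclose(x, 0.0):
        return np.zeros_like(x)
    comps, centers, sos, padlen = _vfcdm_components(x, cfg.analysis_rate, cfg)
    lo, hi = cfg.tvsymp_band
    in_band = (centers >= lo) & (centers <= hi)
    selected = comps[in_band]
    if refine:
        selected = np.array([
            _refine_component(c, fk, cfg.analysis_rate, sos, padlen)
            for c, fk in zip(selected, centers[in_band])
        ])
    s = selected.sum(axis=0)
    if normalize:
        sd = s.std()
        if sd > 0:
            s = s / sd
    return np.abs(sg.hilbert(s))


def mtvsymp(tvs: np.ndarray, rate: float, lookback: float = 5.0) -> np.ndarray:
    """Modified TVSymp: excess of TVSymp over its mean in the preceding
    ``lookback`` seconds, clipped at zero. The first samples use whatever
    partial history exists (the very first sample compares to itself)."""
    tvs = np.asarray(tvs, dtype=float)
    if tvs.size == 0:
        raise ValueError("empty input")
    L = max(int(round(lookback * rate)), 1)
    csum = np.concatenate([[0.0], np.cumsum(tvs)])
    idx = np.arange(tvs.size)
    start = np.maximum(idx - L, 0)
    count = idx - start
    prev_mean = np.where(count > 0, (csum[idx] - csum[start]) / np.maximum(count, 1),
                         tvs)
    return np.maximum(tvs - prev_mean, 0.0)
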