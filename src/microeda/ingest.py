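"""Wristband log ingestion and EDA signal preprocessing.

The DIY wristband measures skin resistance through a voltage divider:
``R_skin = (1 - 2*Vout/Vdd) * Rref`` with ``Vdd = 3.3 V`` and
``Rref = 826 kΩ``, and skin conductance follows as ``G = 1e6 / R_skin`` μS.
This module owns the conversion, the uniform-grid regularization of raw
timestamped samples, and the standard preprocessing chain: polyphase
resampling, zero-phase Butterworth filtering (1.5 Hz low-pass / 0.01 Hz
high-pass), min-max or z-score normalization, moving-average smoothing and
z-score outlier removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal


class NonPhysicalReadingError(ValueError):
    """Voltage at or above Vdd/2 implies zero or negative skin resistance."""


class DegenerateSignalError(ValueError):
    """Operation undefined for a constant (zero-range) signal."""


@dataclass(frozen=True)
class DeviceConfig:
    """Electrical constants of the EDA wristband front-end.

    Defaults are the constants of the DIY unit: 3.3 V supply, 826 kΩ
    reference resistor, 10 Hz ADC rate, 0.80 cm Ag/AgCl electrodes carrying
    1.50 μA.
    """

    supply_voltage: float = 3.3  # V
    reference_resistance: float = 826_000.0  # Ω
    adc_sampling_rate: float = 10.0  # Hz
    electrode_diameter: float = 0.80  # cm
    electrode_current: float = 1.50  # μA

    def __post_init__(self) -> None:
        if self.supply_voltage <= 0:
            raise ValueError("supply_voltage must be positive")
        if self.reference_resistance <= 0:
            raise ValueError("reference_resistance must be positive")
        if self.adc_sampling_rate <= 0:
            raise ValueError("adc_sampling_rate must be positive")
        if self.electrode_diameter <= 0:
            raise ValueError("electrode_diameter must be positive")


@dataclass(frozen=True)
class RawRecording:
    """Timestamped wristband output-voltage samples for one subject."""

    timestamps: np.ndarray  # seconds, monotone non-decreasing
    vout: np.ndarray  # volts
    device: DeviceConfig = field(default_factory=DeviceConfig)
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.vout, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "vout", v)
        if ts.shape != v.shape:
            raise ValueError("timestamps and vout must have the same length")
        if ts.size and np.any(np.diff(ts) < 0):
            raise ValueError("timestamps must be monotone non-decreasing")


@dataclass(frozen=True)
class EDASignal:
    """Uniformly sampled conductance series with processing provenance.

    ``units`` is ``"uS"`` for raw conductance and ``"n.u."`` after
    normalization. Every transform appends a tag to ``provenance``.
    """

    values: np.ndarray
    rate: float  # Hz
    start_time: float = 0.0  # s
    units: str = "uS"
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("signal values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return len(self) / self.rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.rate

    def evolve(self, values: np.ndarray, step: str, *, rate: float | None = None,
               units: str | None = None) -> "EDASignal":
        """Return a copy with new values and a provenance entry appended."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            rate=self.rate if rate is None else rate,
            units=self.units if units is None else units,
            provenance=self.provenance + (step,),
        )


# ---------------------------------------------------------------------------
# voltage ↔ resistance ↔ conductance
# ---------------------------------------------------------------------------

def voltage_to_resistance(vout, device: DeviceConfig):
    """Skin resistance in Ω from output voltage: (1 − 2·Vout/Vdd)·Rref.

    Raises for negative voltages and for readings at or above Vdd/2, which
    would imply non-positive resistance.
    """
    v = np.asarray(vout, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative output voltage is not a valid sample")
    if np.any(v >= device.supply_voltage / 2):
        raise NonPhysicalReadingError(
            "vout >= Vdd/2 implies zero or negative skin resistance"
        )
    r = (1.0 - 2.0 * v / device.supply_voltage) * device.reference_resistance
    return r if r.ndim else float(r)


def resistance_to_conductance(rskin):
    """Skin conductance in μS from resistance in Ω: 1e6 / R."""
    r = np.asarray(rskin, dtype=float)
    if np.any(r <= 0):
        raise ValueError("skin resistance must be strictly positive")
    g = 1e6 / r
    return g if g.ndim else float(g)


def conductance_to_voltage(g_us, device: DeviceConfig):
    """Inverse of the acquisition chain: conductance in μS → Vout in volts.

    Used by the synthetic generator. Valid only while R_skin < Rref, i.e.
    G > 1e6/Rref μS; otherwise the divider would need a negative voltage.
    """
    g = np.asarray(g_us, dtype=float)
    if np.any(g <= 0):
        raise ValueError("conductance must be positive")
    r = 1e6 / g
    if np.any(r >= device.reference_resistance):
        raise ValueError(
            "conductance too low for the divider: R_skin >= Rref maps to Vout < 0"
        )
    v = (1.0 - r / device.reference_resistance) * device.supply_voltage / 2.0
    return v if v.ndim else float(v)


def electrode_geometry(device: DeviceConfig) -> dict:
    """Electrode contact area (cm²) and current density (μA/cm²)."""
    if device.electrode_current < 0:
        raise ValueError("electrode current must be non-negative")
    area = np.pi * (device.electrode_diameter / 2.0) ** 2
    return {
        "area_cm2": area,
        "current_density_uA_cm2": device.electrode_current / area,
    }


# ---------------------------------------------------------------------------
# raw samples → uniform conductance series
# ---------------------------------------------------------------------------

def raw_to_eda(rec: RawRecording, *, max_gap_s: float = 1.0) -> EDASignal:
    """Convert a raw recording to a uniformly sampled conductance series.

    Samples outside [0, Vdd/2) are masked as invalid; masked gaps up to
    ``max_gap_s`` are bridged by linear interpolation on the conductance
    scale. The output grid runs at the device ADC rate from the first
    timestamp.
    """
    if len(rec.timestamps) < 2:
        raise ValueError("need at least two samples")
    vdd = rec.device.supply_voltage
    valid = (rec.vout >= 0) & (rec.vout < vdd / 2)
    if not np.any(valid):
        raise ValueError("no valid voltage samples in recording")
    t_valid = rec.timestamps[valid]
    r = (1.0 - 2.0 * rec.vout[valid] / vdd) * rec.device.reference_resistance
    g = 1e6 / r

    rate = rec.device.adc_sampling_rate
    n = int(round((rec.timestamps[-1] - rec.timestamps[0]) * rate)) + 1
    grid = rec.timestamps[0] + np.arange(n) / rate
    vals = np.interp(grid, t_valid, g)

    # leave long masked gaps interpolated but flag them in provenance
    gaps = np.diff(t_valid)
    tag = "raw_to_eda"
    if np.any(gaps > max_gap_s):
        tag += f"[gaps>{max_gap_s}s interpolated: {int(np.sum(gaps > max_gap_s))}]"
    return EDASignal(values=vals, rate=rate, start_time=rec.timestamps[0],
                     units="uS", provenance=(tag,))


# ---------------------------------------------------------------------------
# preprocessing chain
# ---------------------------------------------------------------------------

def resample(sig: EDASignal, target_rate: float) -> EDASignal:
    """Anti-aliased polyphase resampling to ``target_rate`` Hz."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if len(sig) < 2:
        raise ValueError("signal too short to resample")
    if np.isclose(target_rate, sig.rate):
        return sig.evolve(sig.values.copy(), f"resample({target_rate}Hz)")
    frac = Fraction(target_rate / sig.rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(sig.values, up, down, padtype="line")
    return sig.evolve(out, f"resample({target_rate}Hz)", rate=float(target_rate))


def _zero_phase_sos(rate: float, cutoff: float, order: int, btype: str):
    """SOS for an order-``order`` zero-phase Butterworth.

    Realized as a forward-backward pass of a half-order design whose corner
    is pre-warped so the combined (squared-magnitude) response is −3 dB at
    ``cutoff``. This keeps high orders numerically stable and preserves the
    half-power convention of a single-pass filter of the nominal order.
    """
    nyq = rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyq} Hz)")
    half = max(order // 2, 1)
    # corner adjustment in the prewarped (analog prototype) domain so the
    # combined forward-backward magnitude is exactly -3 dB at `cutoff`
    k = (np.sqrt(2.0) - 1.0) ** (1.0 / (2.0 * half))
    w = np.tan(np.pi * cutoff / rate)
    wc = w / k if btype == "lowpass" else w * k
    fc = min(np.arctan(wc) * rate / np.pi, nyq * 0.999)
    return signal.butter(half, fc, btype=btype, fs=rate, output="sos")


def _sosfiltfilt(sos, x: np.ndarray) -> np.ndarray:
    padlen = min(3 * (2 * len(sos) + 1), max(len(x) - 2, 0))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def butter_lowpass(sig: EDASignal, cutoff: float = 1.5, order: int = 32) -> EDASignal:
    """Zero-phase Butterworth low-pass (default 1.5 Hz, effective order 32)."""
    sos = _zero_phase_sos(sig.rate, cutoff, order, "lowpass")
    return sig.evolve(_sosfiltfilt(sos, sig.values), f"lowpass({cutoff}Hz,o{order})")


def butter_highpass(sig: EDASignal, cutoff: float = 0.01, order: int = 8) -> EDASignal:
    """Zero-phase Butterworth high-pass (default 0.01 Hz, effective order 8)."""
    sos = _zero_phase_sos(sig.rate, cutoff, order, "highpass")
    return sig.evolve(_sosfiltfilt(sos, sig.values), f"highpass({cutoff}Hz,o{order})")


def normalize(sig: EDASignal, method: str = "minmax") -> EDASignal:
    """Scale a signal to [0, 1] (min-max, default) or to zero mean/unit SD."""
    x = sig.values
    if method == "minmax":
        rng = x.max() - x.min()
        if rng == 0:
            raise DegenerateSignalError("min-max normalization of a constant signal")
        out = (x - x.min()) / rng
    elif method == "zscore":
        sd = x.std()
        if sd == 0:
            raise DegenerateSignalError("z-score normalization of a constant signal")
        out = (x - x.mean()) / sd
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return sig.evolve(out, f"normalize({method})", units="n.u.")


def moving_average(sig: EDASignal, window_seconds: float) -> EDASignal:
    """Centered moving-average smoothing with edge replication."""
    n = max(int(round(window_seconds * sig.rate)), 1)
    out = ndimage.uniform_filter1d(sig.values, size=n, mode="nearest")
    return sig.evolve(out, f"moving_average({window_seconds}s)")


def remove_outliers_zscore(samples, threshold: float = 3.0):
    """Drop samples with |z| > threshold; returns (kept values, keep mask)."""
    x = np.asarray(samples, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(threshold):
        mask = np.ones(x.shape, dtype=bool)
    else:
        z = (x - x.mean()) / sd
        mask = np.abs(z) <= threshold
    return x[mask], mask


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

#: canonical environment-log column order
ENV_COLUMNS = ["Sound", "Visible", "IR", "UV", "Temperature", "Humid",
               "Pressure", "CO2", "PM1", "PM2.5", "PM10", "Wind"]

_ADC_FULL_SCALE = 2.048  # V, ±2.048 V programmable-gain setting
_ADC_COUNTS = 32768  # 16-bit signed


def read_wristband_csv(path, device: DeviceConfig | None = None,
                       subject_id: str = "S0") -> RawRecording:
    """Read a wristband log CSV.

    Accepts either ``timestamp_iso8601, vout_volts`` or
    ``timestamp_iso8601, adc_code`` (16-bit ADC at ±2.048 V full scale).
    """
    df = pd.read_csv(path)
    device = device or DeviceConfig()
    ts = pd.to_datetime(df["timestamp_iso8601"])
    seconds = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    if "vout_volts" in df.columns:
        v = df["vout_volts"].to_numpy(dtype=float)
    elif "adc_code" in df.columns:
        v = df["adc_code"].to_numpy(dtype=float) * _ADC_FULL_SCALE / _ADC_COUNTS
    else:
        raise ValueError(f"{path}: expected a vout_volts or adc_code column")
    return RawRecording(timestamps=seconds, vout=v, device=device,
                        subject_id=subject_id)


def write_eda_csv(sig: EDASignal, path) -> None:
    pd.DataFrame({"t": sig.times(), "eda": sig.values}).to_csv(path, index=False)


def read_eda_csv(path, rate: float | None = None) -> EDASignal:
    df = pd.read_csv(path)
    t = df["t"].to_numpy(dtype=float)
    if rate is None:
        dt = np.median(np.diff(t))
        rate = 1.0 / dt
    return EDASignal(values=df["eda"].to_numpy(dtype=float), rate=float(rate),
                     start_time=float(t[0]), provenance=(f"read({Path(path).name})",))


def read_environment_csv(path) -> pd.DataFrame:
    """Read an environment log; returns a DataFrame with a ``t`` column in s."""
    df = pd.read_csv(path)
    if "timestamp_iso8601" in df.columns:
        ts = pd.to_datetime(df["timestamp_iso8601"])
        df = df.drop(columns=["timestamp_iso8601"])
        df.insert(0, "t", (ts - ts.iloc[0]).dt.total_seconds().to_numpy())
    missing = [c for c in ENV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing environment columns {missing}")
    return df
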