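"""Synthetic wristband, environment and self-report streams with ground truth.

The generator emulates the study protocol: a two-hour session split into
eight 15-min windows, each with randomized microclimate setpoints and a
math-task difficulty, a few easy/baseline windows among them. A latent
stress level per window — a logistic function of standardized temperature,
CO2 and task difficulty — drives the SCR event rate, the tonic conductance
level and the integer self-reports. Skin conductance is synthesized as

    tonic (baseline + slow drift + thermoregulatory oscillation)
    + sum of biexponential SCRs at Poisson event times
    + Gaussian sensor noise

and converted through the wristband's inverse divider formula to voltage
samples, so the whole pipeline can be exercised from raw volts with every
intermediate quantity known.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sg

from microeda.decompose import biexp_filter_coeffs
from microeda.ingest import (
    ENV_COLUMNS,
    DeviceConfig,
    RawRecording,
    conductance_to_voltage,
    raw_to_eda,
    resample,
)

#: realistic indoor ranges used to draw per-window environmental setpoints
ENV_RANGES = {
    "Sound": (40.0, 80.0),      # a.u.
    "Visible": (100.0, 1000.0),  # a.u.
    "IR": (50.0, 500.0),         # a.u.
    "UV": (0.5, 5.0),            # a.u.
    "Temperature": (20.0, 32.0),  # °C
    "Humid": (30.0, 70.0),       # %RH
    "Pressure": (1000.0, 1020.0),  # hPa
    "CO2": (500.0, 2000.0),      # ppm
    "PM1": (5.0, 40.0),          # μg/m³
    "PM2.5": (10.0, 60.0),       # μg/m³
    "PM10": (20.0, 80.0),        # μg/m³
    "Wind": (0.0, 2.0),          # m/s
}


@dataclass(frozen=True)
class SessionDesign:
    """Protocol of one session: window layout, tasks and setpoints.

    Defaults follow the experiment: 8 contiguous 15-min windows, hard math
    tasks in most windows, an initial baseline period and two easy windows.
    ``setpoints`` may fix the per-window environment; otherwise it is drawn
    uniformly from :data:`ENV_RANGES` with the design seed.
    """

    n_windows: int = 8
    window_s: float = 900.0
    difficulties: tuple | None = None
    baseline_windows: tuple = (0,)
    setpoints: pd.DataFrame | None = None
    seed: int = 0

    #: default task schedule, cycled to the window count: an easy baseline
    #: start, mostly hard tasks, two easy windows
    _DEFAULT_SCHEDULE = (1, 8, 2, 9, 7, 2, 9, 8)

    def __post_init__(self) -> None:
        if self.difficulties is None:
            sched = tuple(self._DEFAULT_SCHEDULE[i % len(self._DEFAULT_SCHEDULE)]
                          for i in range(self.n_windows))
            object.__setattr__(self, "difficulties", sched)
        if len(self.difficulties) != self.n_windows:
            raise ValueError("need one difficulty per window")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")

    @property
    def duration(self) -> float:
        return self.n_windows * self.window_s

    def drawn_setpoints(self) -> pd.DataFrame:
        if self.setpoints is not None:
            return self.setpoints
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 101]))
        data = {c: rng.uniform(lo, hi, size=self.n_windows)
                for c, (lo, hi) in ENV_RANGES.items()}
        return pd.DataFrame(data)


@dataclass(frozen=True)
class EffectModel:
    """How environment and task load map to latent stress and to EDA.

    Latent stress s in (0,1) is a logistic function of standardized
    temperature, CO2 and difficulty; the SCR rate interpolates between
    ``scr_rate_low`` and ``scr_rate_high`` per minute, the tonic level
    between ``tonic_base`` and ``tonic_base + tonic_stress_gain`` μS.
    """

    w_temperature: float = 0.5
    w_co2: float = 0.5
    w_difficulty: float = 3.0
    scr_rate_low: float = 3.0   # /min at s=0
    scr_rate_high: float = 20.0  # /min at s=1
    tonic_base: float = 2.0     # μS
    tonic_stress_gain: float = 1.0  # μS
    drift_slope: float = 2e-4   # μS/s
    osc_amplitude: float = 0.03  # μS, thermoregulatory oscillation
    osc_freq: float = 0.02      # Hz, < 0.05 Hz by construction
    noise_sd: float = 0.01      # μS
    report_noise: float = 0.4   # SD of latent noise behind integer reports

    def latent_stress(self, temperature, co2, difficulty) -> np.ndarray:
        def z(x):
            x = np.asarray(x, dtype=float)
            sd = x.std()
            return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

        d = (np.asarray(difficulty, dtype=float) - 5.5) / 2.7
        eta = (self.w_difficulty * d + self.w_temperature * z(temperature)
               + self.w_co2 * z(co2))
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class SessionTruth:
    """Ground truth behind one generated session."""

    scr_times: np.ndarray       # s, within the session
    scr_amplitudes: np.ndarray  # μS
    tonic: np.ndarray           # μS at the EDA rate
    rate: float                 # Hz of the tonic array
    window_s: float
    window_scr_rates: np.ndarray  # /min per window
    window_stress: np.ndarray | None = None  # latent s per window
    env_setpoints: pd.DataFrame | None = None
    reports: pd.DataFrame | None = None
    noise_sd: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class SessionData:
    """The generated triplet plus its truth."""

    recording: RawRecording
    environment: pd.DataFrame
    reports: pd.DataFrame
    truth: SessionTruth


def scr_kernel(rate: float, tau0: float = 2.0, tau1: float = 0.7):
    """(b, a, peak) of the discrete biexponential SCR response."""
    b, a = biexp_filter_coeffs(tau0, tau1, rate)
    imp = sg.lfilter(b, a, np.r_[1.0, np.zeros(int(20 * tau0 * rate))])
    return b, a, float(imp.max())


def generate_eda(
    window_scr_rates,
    window_tonic,
    *,
    window_s: float = 900.0,
    rate: float = 10.0,
    seed: int = 0,
    tau0: float = 2.0,
    tau1: float = 0.7,
    amp_mu: float = -1.2,
    amp_sigma: float = 0.4,
    noise_sd: float = 0.01,
    drift_slope: float = 2e-4,
    osc_amplitude: float = 0.03,
    osc_freq: float = 0.02,
    shape_mismatch: bool = False,
    device: DeviceConfig | None = None,
    subject_id: str = "S0",
) -> tuple[RawRecording, SessionTruth]:
    """Generate one conductance session and its raw voltage recording.

    ``window_scr_rates`` are SCR events per minute for each window;
    ``window_tonic`` the per-window tonic level in μS (smoothed across
    window boundaries). ``shape_mismatch=True`` generates SCRs with
    inflated time constants to probe decomposition robustness.
    """
    if rate < 4:
        raise ValueError("rate must be >= 4 Hz")
    rates = np.asarray(window_scr_rates, dtype=float)
    tonic_levels = np.asarray(window_tonic, dtype=float)
    if rates.shape != tonic_levels.shape:
        raise ValueError("window_scr_rates and window_tonic must align")
    n_windows = rates.size
    n = int(round(n_windows * window_s * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))

    # tonic: per-window levels smoothed over ~60 s, plus drift + oscillation
    levels = np.repeat(tonic_levels, int(round(window_s * rate)))[:n]
    tonic = ndimage.gaussian_filter1d(levels, sigma=60 * rate, mode="nearest")
    tonic = tonic + drift_slope * t + osc_amplitude * np.sin(2 * np.pi * osc_freq * t)

    # SCR train: Poisson times per window, log-normal peak amplitudes
    times, amps = [], []
    for w in range(n_windows):
        lam = rates[w] * window_s / 60.0
        k = rng.poisson(lam)
        times.append(rng.uniform(w * window_s, (w + 1) * window_s, size=k))
        amps.append(rng.lognormal(amp_mu, amp_sigma, size=k))
    scr_times = np.concatenate(times)
    order = np.argsort(scr_times)
    scr_times = scr_times[order]
    scr_amps = np.concatenate(amps)[order]

    g_tau0, g_tau1 = (tau0 * 1.5, tau1 * 1.3) if shape_mismatch else (tau0, tau1)
    b, a, peak = scr_kernel(rate, g_tau0, g_tau1)
    driver = np.zeros(n)
    idx = np.clip((scr_times * rate).round().astype(int), 0, n - 1)
    np.add.at(driver, idx, scr_amps / peak)
    phasic = sg.lfilter(b, a, driver)

    g = tonic + phasic + rng.normal(0.0, noise_sd, size=n)
    device = device or DeviceConfig(adc_sampling_rate=rate)
    vout = conductance_to_voltage(g, device)
    rec = RawRecording(timestamps=t, vout=np.asarray(vout), device=device,
                       subject_id=subject_id)
    truth = SessionTruth(scr_times=scr_times, scr_amplitudes=scr_amps,
                         tonic=tonic, rate=rate, window_s=window_s,
                         window_scr_rates=rates, noise_sd=noise_sd, seed=seed)
    return rec, truth


def generate_environment(design: SessionDesign, rate: float = 1.0,
                         seed: int = 0, *, ar_phi: float = 0.95,
                         fluctuation_scale: float = 0.02) -> pd.DataFrame:
    """1 Hz environment log: per-window setpoints + AR(1) fluctuation.

    ``fluctuation_scale`` is the innovation SD as a fraction of each
    variable's realistic range; zero gives stepwise-constant traces.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    sp = design.drawn_setpoints()
    n_per = int(round(design.window_s * rate))
    n = n_per * design.n_windows
    out = {"t": np.arange(n) / rate}
    for col in ENV_COLUMNS:
        lo, hi = ENV_RANGES[col]
        base = np.repeat(sp[col].to_numpy(), n_per)
        if fluctuation_scale > 0:
            innov = rng.normal(0.0, fluctuation_scale * (hi - lo), size=n)
            ar = sg.lfilter([1.0], [1.0, -ar_phi], innov)
            # stationary scaling so the fluctuation SD matches the innovation SD
            ar *= np.sqrt(1 - ar_phi ** 2)
            base = base + ar
        out[col] = base
    return pd.DataFrame(out)


def generate_session(design: SessionDesign | None = None,
                     effect: EffectModel | None = None,
                     seed: int = 0, *, eda_rate: float = 10.0,
                     env_rate: float = 1.0,
                     device: DeviceConfig | None = None,
                     subject_id: str = "S0") -> SessionData:
    """Generate the full triplet (wristband, environment, self-reports).

    Latent stress per window couples the drawn environment and the task
    schedule to the SCR rate, the tonic level and the integer reports, so
    windows with hard tasks come out as labeled high-stress with high
    probability and the configured environment→EDA effect directions are
    recoverable by the downstream screening.
    """
    design = design or SessionDesign(seed=seed)
    effect = effect or EffectModel()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))

    sp = design.drawn_setpoints()
    difficulties = np.asarray(design.difficulties, dtype=float)
    s = effect.latent_stress(sp["Temperature"], sp["CO2"], difficulties)

    scr_rates = effect.scr_rate_low + (effect.scr_rate_high - effect.scr_rate_low) * s
    tonic_levels = effect.tonic_base + effect.tonic_stress_gain * s

    rec, truth = generate_eda(
        scr_rates, tonic_levels, window_s=design.window_s, rate=eda_rate,
        seed=seed, noise_sd=effect.noise_sd, drift_slope=effect.drift_slope,
        osc_amplitude=effect.osc_amplitude, osc_freq=effect.osc_freq,
        device=device, subject_id=subject_id,
    )
    env = generate_environment(design, rate=env_rate, seed=seed)

    def report(scale_max, center):
        noise = rng.normal(0.0, effect.report_noise, size=design.n_windows)
        return np.clip(np.round(center + noise), 1, scale_max).astype(int)

    reports = pd.DataFrame({
        "subject": subject_id,
        "window": np.arange(design.n_windows),
        "difficulty": difficulties.astype(int),
        "stress": report(7, 1 + 6 * s),
        "valence": report(9, 9 - 8 * s),
        "arousal": report(9, 1 + 8 * s),
        "dominance": report(9, 9 - 4 * s),
        "is_baseline": [w in design.baseline_windows
                        for w in range(design.n_windows)],
    })
    truth = replace(truth, window_stress=s, env_setpoints=sp, reports=reports)
    return SessionData(recording=rec, environment=env, reports=reports,
                       truth=truth)


def noise_sd_for_rho(values, rho: float) -> float:
    """Noise SD that attenuates correlation with a clean copy to ``rho``:
    rho = 1/sqrt(1 + sd²/var(values)).

    ``values`` should be the trace *as it enters the comparison* — i.e. the
    preprocessed (resampled/filtered/smoothed) conductance — since
    preprocessing changes the signal variance the formula refers to.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    var = float(np.var(np.asarray(values, dtype=float)))
    return float(np.sqrt(var * (1.0 / rho ** 2 - 1.0)))


def _lowband_noise(n: int, rate: float, sd: float, bandwidth: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise band-limited to ``bandwidth`` Hz, rescaled to ``sd``.

    Device disagreement is dominated by slow contact/drift differences, so
    the comparison noise lives below the preprocessing passband edge and
    survives filtering/smoothing — the analytic attenuation formula then
    applies to the processed traces as well.
    """
    white = rng.normal(0.0, 1.0, size=n)
    sos = sg.butter(4, bandwidth, btype="lowpass", fs=rate, output="sos")
    x = sg.sosfiltfilt(sos, white)
    realized = x.std()
    return x * (sd / realized) if realized > 0 else x


def generate_device_pair(base: RawRecording, *, gain: float = 1.0,
                         offset: float = 0.0, noise_sd: float = 0.0,
                         lag_s: float = 0.0, seed: int = 0,
                         rate_out: float = 4.0,
                         noise_bandwidth: float = 0.05,
                         ) -> tuple[RawRecording, RawRecording]:
    """Emulate a two-wrist device comparison.

    Returns the base recording resampled to ``rate_out`` and an affine-
    transformed (``gain``, ``offset``), lagged, independently-noised copy —
    the "reference device" stream against which the DIY unit is validated.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 59]))
    eda = raw_to_eda(base)
    eda4 = resample(eda, rate_out)
    g = eda4.values
    t = np.arange(g.size) / rate_out
    g_lagged = np.interp(t - lag_s, t, g)
    g2 = gain * g_lagged + offset
    if noise_sd > 0:
        g2 = g2 + _lowband_noise(g.size, rate_out, noise_sd, noise_bandwidth, rng)
    device4 = DeviceConfig(adc_sampling_rate=rate_out,
                           supply_voltage=base.device.supply_voltage,
                           reference_resistance=base.device.reference_resistance)
    rec_a = RawRecording(timestamps=t, vout=np.asarray(
        conductance_to_voltage(g, device4)), device=device4,
        subject_id=base.subject_id)
    rec_b = RawRecording(timestamps=t, vout=np.asarray(
        conductance_to_voltage(np.maximum(g2, 1.3), device4)), device=device4,
        subject_id=base.subject_id + "_ref")
    return rec_a, rec_b
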