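import numpy as np
import pandas as pd
import pytest
from scipy import signal as sg

from microeda import EDASignal, cvxeda_decompose
from microeda.decompose import biexp_filter_coeffs


def make_scr_signal(onsets, amplitudes, *, rate=4.0, duration_s=600.0,
                    baseline=2.0, drift=0.0005, noise_sd=0.01, seed=0):
    """Conductance trace = baseline + drift + known biexponential SCRs + noise.

    Built directly from the SCR kernel so decomposition tests have exact
    ground truth independent of the session generator.
    """
    n = int(duration_s * rate)
    t = np.arange(n) / rate
    b, a = biexp_filter_coeffs(2.0, 0.7, rate)
    imp = sg.lfilter(b, a, np.r_[1.0, np.zeros(n)])
    peak = imp.max()
    driver = np.zeros(n)
    for onset, amp in zip(onsets, amplitudes):
        driver[int(round(onset * rate))] = amp / peak
    phasic = sg.lfilter(b, a, driver)
    rng = np.random.default_rng(seed)
    y = baseline + drift * t + phasic + rng.normal(0, noise_sd, n)
    return EDASignal(values=y, rate=rate), phasic


@pytest.fixture(scope="session")
def scr_fixture():
    """10-min, 4 Hz trace with 5 SCRs of 0.5 μS at known onsets, decomposed."""
    onsets = np.array([60.0, 150.0, 280.0, 400.0, 520.0])
    sig, phasic_true = make_scr_signal(onsets, [0.5] * 5)
    decomp = cvxeda_decompose(sig)
    return {"signal": sig, "onsets": onsets, "phasic_true": phasic_true,
            "decomp": decomp}


@pytest.fixture(scope="session")
def learnable_table():
    """Feature table with a noise-free monotone environment→EDA link, the
    forward/reverse modeling benchmark."""
    rng = np.random.default_rng(7)
    n = 400
    df = pd.DataFrame({
        "subject": np.repeat([f"S{i}" for i in range(5)], n // 5),
        "Temperature": rng.uniform(20, 32, n),
        "CO2": rng.uniform(500, 2000, n),
        "Humid": rng.uniform(30, 70, n),
        "IR": rng.uniform(50, 500, n),
    })
    # deterministic monotone responses (no noise)
    df["SCL"] = 2.0 + 0.12 * (df["Temperature"] - 20) + 8e-4 * (df["CO2"] - 500)
    df["NSSCR"] = 4.0 + 0.5 * (df["Temperature"] - 20)
    df["TVSymp"] = 0.1 + 1e-4 * (df["CO2"] - 500)
    df["shuffled"] = rng.permutation(df["SCL"].to_numpy())
    return df
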