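# microeda

Analysis pipeline linking **microclimate** to **electrodermal activity
(EDA)** from a low-cost sensing wristband: raw output voltage → skin
conductance → tonic/phasic decomposition by convex optimization → six EDA
indices (SCL, NSSCR, dphEDA, EDASymp, TVSymp, MTVSymp) → synchronization
with a 1 Hz environment log → stress-window labeling from self-report →
screening statistics and two-way machine-learning models (environment→EDA
and EDA→environment) with Shapley attribution. A synthetic-session
generator with full ground truth makes every stage testable without
access to participant data.

It is written for researchers in psychophysiology, wearable sensing and
indoor-environment studies who want a reproducible, inspectable
implementation of this analysis rather than a black box.

## The core models

**Acquisition.** The wristband reads skin resistance through a voltage
divider (Vdd = 3.3 V, Rref = 826 kΩ, 10 Hz):

    R_skin = (1 − 2·Vout/Vdd)·Rref,   G_skin = 10⁶ / R_skin  [μS]

**Decomposition.** Conductance y is split into a sparse non-negative
sudomotor driver p convolved with a biexponential SCR response
h(t) = e^(−t/τ₀) − e^(−t/τ₁) (τ₀ = 2 s, τ₁ = 0.7 s), a cubic-spline tonic
term, an affine drift, and noise, by the convex program

    min ½‖y − Mp − Bℓ − Cd‖² + α‖p‖₁ + γ‖ℓ‖²   s.t. p ≥ 0

solved as a bound-constrained QP with the convolution applied as an ARMA
filter (a 2-hour session decomposes in ~20 s).

**Indices.** SCL = 2-min means of the tonic component; NSSCR =
prominence-qualified response peaks per minute; dphEDA = derivative of
the phasic component; EDASymp = normalized 0.045–0.25 Hz spectral power
(128-point Blackman Welch estimate); TVSymp = analytic amplitude of the
0.08–0.24 Hz content via variable frequency complex demodulation;
MTVSymp = max(0, TVSymp − its mean over the preceding 5 s).

**Labeling.** A window is high stress iff difficulty ≥ 7 (of 10) and
stress ≥ 5 (of 7); low iff both ≤ 2 or baseline.

**Screening and models.** Kolmogorov–Smirnov normality check, Fisher's
ratio (μ₁−μ₀)²/(σ₁²+σ₀²), Spearman correlation matrices; random forest /
SVR / linear regression under leave-one-subject-out and repeated 70/30
splits, compared by mean held-out R², with interventional Shapley values
(computed in-package, exact local accuracy) explaining the fitted models
in both directions.

## Worked example

Each script in `examples/` exercises one capability. Decomposition with
known ground truth (`examples/02_decompose_scrs.py`):

```text
true SCR onsets     : [ 60. 150. 280. 400. 520.]
recovered driver pks: [ 60. 150. 280. 400. 520.]
residual energy     : 0.0018 % of signal energy
tonic level (median): 2.147 μS (true baseline 2.0 + drift)
```

All five injected responses are recovered at their exact onsets — the
driver deconvolves the SCR shape, so it marks when sudomotor bursts
happened, not when conductance peaked — and the tonic estimate tracks the
drifting baseline.

Sympathetic indices on known tones (`examples/03_sympathetic_indices.py`):

```text
EDASymp normalized power:
  0.10 Hz tone (in band) : 1.000
  0.50 Hz tone (outside) : 0.000
TVSymp instantaneous amplitude of the 0.10 Hz tone:
  mean 0.509 (the tone's amplitude is 0.500)
  same-amplitude 0.02 Hz tone: 0.0041 (rejected, below the band)
```

Two-device validation with a controllable ground-truth correlation
(`examples/05_device_validation.py`): noise tuned for an analytic ρ of
0.9 yields `Spearman ρ ... over 20 seeds: 0.900 ± 0.011` after the full
preprocessing chain.

`examples/04_stress_study.py` runs a three-subject synthetic study end to
end and prints the stress-class feature summary and the model-comparison
grid; `examples/01_voltage_to_conductance.py` shows the raw conversion
and electrode geometry (0.50 cm², 2.98 μA/cm²).

A command-line interface mirrors the stages:

```bash
microeda simulate --seed 1 --out session/
microeda run --seed 1 --n-subjects 3 --out report/
```

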