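# Methods

`microeda` implements an analysis chain for studying how microclimate
(temperature, humidity, CO2, pressure, light, particulates, wind, sound)
relates to electrodermal activity (EDA) recorded by a low-cost wristband,
together with a synthetic-data generator that provides ground truth for
every stage. This note documents the models, the numerical choices, and
what the synthetic validation does and does not establish.

## Signal acquisition model

The wristband senses skin resistance through a voltage divider against a
reference resistor (Rref = 826 kΩ) at a supply voltage Vdd = 3.3 V,
sampling the output voltage at 10 Hz:

    R_skin = (1 − 2·Vout/Vdd) · Rref        [Ω]
    G_skin = 1e6 / R_skin                   [μS]

Readings at or above Vdd/2 would imply non-positive resistance and are
treated as invalid samples rather than clipped; gaps up to 1 s are bridged
by linear interpolation on the conductance scale, longer gaps are
interpolated too but flagged in the signal's provenance record. The
default electrode configuration (0.80 cm diameter, 1.50 μA) implies a
0.50 cm² contact area and ≈2.98 μA/cm² current density, comfortably below
the 10 μA/cm² safety recommendation.

## Preprocessing

- **Resampling** uses polyphase anti-aliased resampling (`resample_poly`
  with linear-extrapolated padding). Decomposition runs at 4 Hz; spectral
  and sync stages at 2 Hz.
- **Filtering**: the 1.5 Hz low-pass ("32nd order Butterworth") and
  0.01 Hz high-pass (8th order) are realized as zero-phase
  forward–backward passes of half-order second-order-section designs. A
  direct transfer-function implementation of a 32nd-order Butterworth is
  numerically unusable; the forward–backward SOS cascade has the same
  asymptotic roll-off as the nominal order and no phase lag (which matters
  when two devices are compared sample-by-sample). The corner frequency of
  the half-order design is adjusted in the prewarped analog domain so the
  *combined* response is exactly −3 dB at the stated cutoff, preserving
  the half-power convention of the nominal single-pass filter.
- **Normalization** defaults to per-session min-max scaling to [0, 1]
  (z-score available); it errors on constant signals.
- **Smoothing** is a centered moving average with edge replication;
  **outlier removal** drops samples with |z| > 3 (threshold configurable).

## Tonic/phasic decomposition

Conductance is modeled as `y = M p + B ℓ + C d + e`: a non-negative sparse
sudomotor driver `p` convolved with the biexponential SCR impulse response
`h(t) = exp(−t/τ0) − exp(−t/τ1)` (defaults τ0 = 2.0 s, τ1 = 0.7 s), a
cubic B-spline tonic term with knots every 10 s, an affine drift, and
residual noise. The decomposition solves

    min ½‖y − Mp − Bℓ − Cd‖² + α‖p‖₁ + γ‖ℓ‖²   s.t. p ≥ 0

with α = 8e−4 and γ = 1e−2 by default. Because `p ≥ 0` makes the L1 term
linear, the problem is a smooth bound-constrained QP; it is solved with
L-BFGS-B, with `M` applied implicitly as an ARMA filter obtained by the
bilinear transform of `h` (no dense convolution matrix, so a 2-hour 4 Hz
session decomposes in ~15–20 s on one core). The residual is defined as
`y − tonic − phasic`, so the three components reconstruct the input
exactly by construction. Scaling the signal by `a > 0` while scaling α by
`a` (γ unchanged) scales tonic and phasic by `a` (homogeneity, tested).

Driver peaks mark SCR onsets (the driver is the deconvolved input, not
the delayed conductance peak). `driver_peaks` reports local maxima above
10 % of the driver maximum, at least 1 s apart.

## EDA indices

- **SCL**: mean of the tonic component over 2-min windows (also reported
  per 15-min experiment window).
- **NSSCR**: skin conductance responses per minute. Two estimators are
  exposed through the same operation: prominence-qualified local maxima of
  the *phasic* series (min amplitude 0.01 μS, min separation 1 s — the
  classical definition), and peaks of the *driver* series (prominence
  0.05, min separation 0.5 s). The driver estimator deconvolves
  overlapping SCRs and is the one used for rate-recovery validation; at
  18 events/min the phasic estimator systematically merges events whose
  spacing falls under the SCR width, while the driver estimator stays
  within ±2/min of the injected rate down to the 4 Hz grid's resolution
  limit.
- **dphEDA**: central-difference derivative of the phasic component,
  one-sided at the edges.
- **EDASymp**: Welch spectrum of detrended 2 Hz EDA with 128-point
  Blackman segments; band power in 0.045–0.25 Hz, normalized by total
  power above DC. Segment overlap defaults to 50 % (64 samples); the
  literal reading of a "0.5 s overlap" (a single sample of a 64 s window)
  is available by configuration but is spectrally meaningless and not the
  default. Both normalized and raw band power are emitted, since summary
  tables sometimes quote the index in μS².
- **TVSymp**: variable frequency complex demodulation. The signal is
  demodulated at center frequencies spaced 0.03 Hz apart, each component
  extracted with a 6th-order zero-phase low-pass of half-spacing cutoff
  (forward–backward Butterworth power responses at symmetric offsets tile
  the frequency axis to within ~3 %, so a tone split between adjacent
  bins is neither lost nor double-counted). Each component is refined by
  re-demodulating it around its own smoothed instantaneous frequency.
  Components with centers in 0.08–0.24 Hz are summed and TVSymp is the
  analytic (Hilbert) amplitude of that sum; a unit-variance normalization
  of the in-band reconstruction is available for cross-subject
  comparison. Amplitude accuracy on a single in-band tone is within ~2 %
  at bin centers and degrades toward bin midpoints; the test suite asserts
  ±10 %.
- **MTVSymp**: `max(0, TVSymp(t) − mean(TVSymp over [t−5 s, t)))`,
  computed with a running sum; the first samples use the available
  partial history and the very first sample compares to itself (zero).

## Labeling and synchronization

Self-reports per 15-min window carry task difficulty (1–10), stress (1–7)
and SAM valence/arousal/dominance. A window is labeled **high** stress
when difficulty ≥ 7 and stress ≥ 5, **low** when both ratings are ≤ 2 or
the window is a baseline period, otherwise **unlabeled**. A lenient
variant (> 6 / > 4 for high, < 3 for low) is selectable; the strict rule
is the operational default because it is the stated experiment rule.
STAI/appraisal/TLX items are carried raw, not scored.

Environment logs (~1 Hz) are joined onto the 2 Hz EDA feature rows by
carrying the last known environment sample forward, with gaps over 2 s
left missing; EDA rows inside the overlapping time range are never
duplicated or dropped.

## Statistics

Fisher's ratio `(μ_high − μ_low)² / (σ²_high + σ²_low)` uses unbiased
variances; summary tables report the mean and max of per-subject ratios
plus pooled class means ± SD. The KS normality check estimates the normal
parameters from the sample (no Lilliefors correction) since it only
motivates using Spearman rather than Pearson correlation; its p-value is
reported as approximate. Spearman correlation uses average ranks for
ties; correlation matrices follow the declared variable order and pool
subjects (per-subject sensitivity analysis is possible since subject ids
are retained).

## Models and attribution

Random forest (500 trees by default; reduced in bundled examples and
validation runs for speed), RBF-kernel SVR (standardized inputs, C = 1,
ε = 0.1) and OLS are evaluated with held-out R² under two schemes:
leave-one-subject-out (one fold per subject, the held-out subject's rows
excluded from training) and 70/30 shuffle splits. A single split has no
"mean cross-validation" score, so the 70/30 scheme averages 5 seeded
repeats (configurable). Negative R² values are reported as-is. Forward
models map the 12 environment columns to each EDA index; reverse models
map the six EDA indices to temperature, CO2, humidity and IR.

Shapley attributions are computed in-package with the interventional
value function v(S) = E_b[f(x_S, b_~S)] over a fixed-seed background
sample: a closed form for linear models, full subset enumeration when
2^k·|background|·|instances| is affordable (k ≤ ~12 features), and a
fixed-seed permutation estimator otherwise. All three satisfy local
accuracy — attributions plus baseline equal the model prediction — the
permutation estimator exactly so, because each sampled ordering's
marginal contributions telescope.

## Synthetic data generator

The generator emulates the study protocol: eight 15-min windows with
randomized environmental setpoints drawn from realistic indoor ranges
(e.g. 20–32 °C, 500–2000 ppm CO2), AR(1) within-window fluctuation, a
task schedule with mostly hard windows plus baseline/easy ones, and a
latent stress level per window

    s = logistic(w_d·(difficulty−5.5)/2.7 + w_T·z(temperature) + w_C·z(CO2))

with defaults w_d = 3, w_T = w_C = 0.5. Latent stress drives the SCR rate
(3–20 events/min), the tonic level (2–3 μS), and the integer self-reports
(discretized logistic-noise mappings clipped to scale bounds), so hard
windows satisfy the high-stress labeling rule with probability ≥ 0.9 and
each configured environment→EDA effect direction is recoverable by
Spearman screening. Conductance is tonic (baseline + 0.2 mμS/s drift + a
0.02 Hz, 0.03 μS thermoregulatory oscillation) plus biexponential SCRs at
Poisson event times with LogNormal(−1.2, 0.4) μS amplitudes plus Gaussian
noise (SD 0.01 μS), inverted through the divider formula to voltage
samples. SCRs reuse the decomposition's kernel so recovery is well-posed;
a shape-mismatch mode (inflated time constants) exists for robustness
tests. All generators are pure functions of (parameters, seed).

The two-device comparison generator produces an affine-transformed,
lagged, independently-noised copy of a recording at 4 Hz. Its noise is
band-limited below 0.05 Hz — modeling the slow contact-quality and
placement drift that actually distinguishes two wrists — so the analytic
attenuation ρ = 1/√(1 + σ²/var) remains observable after the validation
pipeline's own low-pass and smoothing. `noise_sd_for_rho` should be fed
the *preprocessed* trace, whose variance is the one the formula refers
to.

### What the synthetic validation shows — and does not

Passing recovery tests establishes that the pipeline is a faithful
inverse of the generative model: onset deconvolution, rate and level
recovery, band selectivity, label logic, evaluation isolation. Real
recordings differ in ways the generator does not emulate: motion and
pressure artifacts, electrode drift and detachment, non-biexponential and
amplitude-dependent SCR shapes, breathing/vasomotor interference in the
sympathetic bands, reporting biases in self-report. Results on synthetic
sessions therefore validate the *software*, not the physiological claims;
effect sizes and model R² on real data are not predicted by these tests.

## Problem sizes and numerical choices

Bundled examples and validation runs use scaled-down sessions (e.g. three
subjects, 5-min windows, 100-tree forests); every window is still long
enough for all stages (spectral indices need ≥ 64 s of 2 Hz signal,
TVSymp ≥ 60 s, the decomposition ≥ 4 knot spacings). The L-BFGS-B solver
runs to a 1e−9 relative objective tolerance with up to 4000 iterations;
decomposition results are deterministic given inputs. Degenerate inputs
(constant series for normalization/Spearman/KS, single-subject LOSO,
disjoint time ranges) raise errors rather than returning silent NaNs.

## Known limitations

- The driver-based SCR counter undercounts when event spacing falls below
  ~0.5 s (the 4 Hz deconvolution limit); at 18 events/min this bias is
  about −1.5/min.
- TVSymp amplitude has a small positive bias (≲5 %) for tones between
  demodulation bin centers.
- The KS p-value ignores parameter estimation and is only a screening
  heuristic.
- LOSO with few synthetic subjects has high fold variance; the grid's
  purpose is comparative ranking, not absolute skill estimates.
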