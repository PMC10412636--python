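# Methods

This note documents the models implemented in `fluorobind`, the
numerical choices behind them, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Quenching titrations

Three intensity models are supported, each with an exact algebraic
inverse used by the generator:

| model | forward form | estimator |
|---|---|---|
| Stern–Volmer | `F = F0/(1 + K_SV[Q])` | OLS of `F0/F` vs `[Q]`; `K_SV` = slope |
| power binding | `F = F0/(1 + K_b[Q]^n)` | OLS of `log10((F0−F)/F)` vs `log10[Q]`; `n` = slope, `K_b = 10^intercept` |
| membrane partition | `(F0/F) − 1 = L[Q]/(K_d + [Q])` | OLS of `1/((F0/F)−1)` vs `1/[Q]`; `K_d = slope/intercept` |

Because all three estimators are linear in their transformed variables,
noiseless generator→estimator round trips are exact to floating-point
precision; this is the basis of the parameter-recovery acceptance
checks.

Conventions and choices:

- **Units.** Stern–Volmer and double-log fits consume molar
  concentrations (constants in 1/M, matching how such constants are
  tabulated); the partition fit returns `K_d` in whatever unit the
  titration declares (µM by convention). The lipid concentration `L`
  enters the partition model as a dimensionless scale and cancels in
  `slope/intercept`, so its physical unit (mg/mL) never matters — a
  property the tests assert directly.
- **Noise model.** Detected intensities get multiplicative lognormal
  noise parameterised by a coefficient of variation (unit mean, keeps
  `F > 0`, matches photodetector behaviour at these signal levels).
  The CV and seed live in the ground-truth object; seeded runs are
  bit-reproducible.
- **Log base.** Base 10 in the double-log fit, the convention for this
  plot.
- **Stern–Volmer intercept** is fitted freely; its deviation from 1 is
  a useful diagnostic (static quenching, calibration error). A
  forced-unit-intercept variant is available.
- **Inner-filter correction** (`F_obs·10^{(A_ex+A_em)/2}`) is applied
  by default when absorbances are supplied (CLI `--no-ifc` opts out).
- **Points with F ≥ F0** are impossible under all three models but
  occur under noise; partition and double-log fits exclude them and
  report their indices rather than erroring or silently dropping them.
  A fitted line with non-positive slope or intercept in the partition
  fit implies `K_d ≤ 0` and raises a non-physical-fit error carrying
  the raw coefficients.
- **Replicates** are averaged per concentration before fitting (the
  default); per-replicate fits are available for spread/SD estimation.
  A caveat the tests quantify: the reciprocal transform inflates the
  variance of low-concentration points, so single-replicate partition
  fits under ≥5% noise at shallow quench depth are unstable and biased.
  With four replicates averaged per concentration and a quench depth of
  ~60% the median estimate over many datasets is within 2% of truth.
  The unweighted OLS (rather than variance-weighted) follows the
  simple-linear-graph convention these analyses traditionally use.

## Anisotropy

`A = (I∥ − G·I⊥)/(I∥ + 2G·I⊥)`, with the instrument G factor
supplied per reading. The estimator is scale-invariant and bounded in
[−0.5, 1]; a zero total intensity is a degenerate-input error. The
generator inverts the formula exactly: `I∥ = I_tot(1+2A)/3`,
`I⊥ = I_tot(1−A)/(3G)`.

## FCS

### Photon-stream simulation

Point emitters diffuse by Brownian steps (per-axis step
`N(0, √(2D·dt))`) in a periodic box, default
`(10w0, 10w0, 10κw0)`, with the detection profile
`exp(−2r²/w0² − 2z²/(κw0)²)` centred in the box. Per step each
emitter contributes Poisson photons with mean
`brightness·dt·profile`; macro-times are jittered uniformly within the
step. Signal photons carry micro-times `offset + Exp(τ)` wrapped into
the pulse period (default 25 ns, i.e. 40 MHz); background photons are
uniform in time and micro-time. Validity guards: `dt` small enough
that the rms step is ≤ w0/5, every box side ≥ 10 w0, duration ≥ 100
diffusion times.

Implied ground truths: `t_D = w0²/(4D)` and
`PN = ρ·π^{3/2}w0²(κw0)` with `ρ` the realized number density. The
particle count is the nearest integer to `c·N_A·V_box` (a canonical
ensemble; occupancy of the far smaller detection volume remains
effectively Poissonian, and the ≤0.5-particle rounding keeps the PN
ground truth deterministic per run — 0.08% at the 1 nM calibration).
An `emitters_per_molecule` factor models an extended, multiply-labelled
molecule (a relaxed plasmid) as several independent point emitters,
which reproduces the qualitative PN overestimation seen for unfolded
DNA; this is a deliberate simplification — segments of a real coil are
hydrodynamically coupled and a coil's tD is not a point particle's.

Not emulated: triplet blinking, photobleaching and saturation (the
low-excitation regime these measurements use justifies the omission),
detector afterpulsing and dead time, anomalous diffusion.

### Correlation

Both correlators work on the binned count trace and exclude zero lag
(so no shot-noise correction is needed), with symmetric normalization
`G(k) = ⟨I_i I_{i+k}⟩/(⟨I⟩_left⟨I⟩_right) − 1` to suppress drift bias.
The `direct` scheme evaluates this exactly at every requested lag and
serves as the reference; `multi_tau` uses 8 channels per cascade and
rebins the trace by 2 between cascades. On the same stream the two are
identical on the first cascade and differ only by the triangular
smoothing of rebinning afterwards; across all shared lags the deviation
stays within 2% of the G(0) amplitude (the equivalence metric used,
because a pointwise ratio is ill-conditioned in the tail where both
estimators fluctuate around zero).

### Diffusion fit

One-component 3D Gaussian-volume model
`G(τ) = (1/N)(1+τ/t_D)⁻¹(1+τ/(κ²t_D))^(−1/2)`, least squares via
lmfit, weights from per-lag standard errors when present. `PN = 1/G(0)`
by construction. κ is fixed at 5 by default — the calibration, together
with `w0 = 0.35 µm`, consistent with an effective volume of ~1.2 fL and
hence PN ≈ 0.72 at 1 nM; instrument calibrations vary and both are
overridable. No triplet term (single-tD samples at low power). Initial
guesses come from the short-lag amplitude and the half-amplitude lag;
non-convergence is returned as a flag, never silently.

### Lifetime

Tail-fit maximum likelihood on micro-times at or beyond a window start
(default 0.5 ns past the peak channel, sidestepping IRF modelling — an
80 ps excitation pulse is negligible against 2–4 ns lifetimes): mixture
of a truncated exponential and a uniform background on the window,
minimized over `(log τ, logit b)` by Nelder–Mead. An exponential
wrapped into the pulse period remains proportional to `exp(−t/τ)` on
the period, so the truncated-window likelihood is exact even when τ is
not small against the period. At 10⁵ photons the estimator's bias is
below 0.02 ns and its SE ~0.015 ns, comfortably inside the ±0.1 ns
precision such lifetimes are reported with.

### Folding classification

`expected_particle_number(c, w0, κ)` gives the concentration-implied
PN. A fitted PN within ±0.1 of it classifies the molecule as `folded`
(diffusing as one point-like particle); PN ≥ 3× expected is `relaxed`
(many labelled segments contributing quasi-independent fluctuations);
anything between is `intermediate`.

## ATR-FTIR

Band maxima are extracted per named wavenumber window (defaults:
choline ν_as(N–C) 960–980, ν_s(PO₂⁻) 1040–1110, ν_as(PO₂⁻) 1190–1260,
ν(C=O) 1700–1780, ν_s(CH₂) 2840–2870, ν_as(CH₂) 2905–2940 cm⁻¹;
phosphate and carbonyl windows allow two subbands for split-band
detection). Procedure: rubber-band (lower convex hull) baseline
subtraction over the **full spectrum** — over the full range each band
decays to baseline, so the hull chord is flat beneath it; a
window-local hull would subtract a tilted chord and bias the maximum by
slope·σ² — then prominence-filtered local maxima (threshold relative to
the window's corrected amplitude, making positions invariant under
positive scaling and linear baselines), refined by three-point
parabolic interpolation. At 0.5 cm⁻¹ sampling of a 10 cm⁻¹-FWHM band
the refinement error is below 0.005 cm⁻¹. Band shifts are
dominant-peak differences (sample − control); a missing band raises an
error naming which spectrum lacked it. FWHM of the corrected band is
available as a secondary broadening diagnostic. No second-derivative or
Fourier self-deconvolution resolution enhancement is attempted — peak
maxima are the reported quantity.

## Statistics

One-way ANOVA by the classical between/within decomposition
(all-identical data returns F=0, p=1 rather than 0/0). Duncan's
multiple range test compares the extremes of each span of p sorted
means against `R_p = q_{α_p,p,df}·√(MSE/n_h)` with the protection
level `α_p = 1−(1−α)^{p−1}`; quantiles come from the studentized-range
distribution numerically (no tables) and are cached, since a single ppf
evaluation costs ~0.2 s. Spans inside a homogeneous range are never
retested, making homogeneous sets contiguous intervals of the sorted
means; letters label the maximal intervals, and a group is flagged vs
control exactly when it shares no letter with it. Unbalanced designs
use the harmonic mean of group sizes. At span 2 the protection level
equals α, so two-group decisions coincide with Fisher's LSD — asserted
in the tests. Duncan's procedure is known to be liberal: under a global
null the per-comparison vs-control flag rate sits near 5–6% (the test
bounds it in [3%, 8%]).

## Problem sizes in the test suite

The acceptance suite simulates one 60 s photon stream at the 1 nM
calibration condition and reuses it for both the diffusion-time and the
particle-number checks (they describe the same measurement). The
end-to-end recovery property uses twenty 2 s streams at a 0.2 ms
diffusion time — 10⁴ volume crossings per stream keeps estimator
scatter well inside the ±10% tolerance. ANOVA type-I calibration runs
10⁴ null datasets in the acceptance suite and 4000 in the unit test;
the Duncan flag-rate property uses 1500.

## Known limitations

- The partition, Stern–Volmer and double-log estimators are the
  classical linearized forms, chosen for comparability with how such
  constants are tabulated; a nonlinear fit of the raw intensities would
  weight noise more evenly and is not provided.
- The FCS model is strictly one-component normal diffusion without
  triplet kinetics; curves from mixtures or anomalous transport will
  fit poorly (the honest convergence/χ² fields are the guard).
- The lifetime model is mono-exponential plus flat background;
  multi-exponential decays return an amplitude-weighted compromise.
- The plasmid-as-k-emitters picture reproduces PN inflation
  qualitatively only; it does not model the coil's internal dynamics.
- Duncan's test is implemented as specified for its historical role in
  this literature; its liberal error control is documented, not fixed.
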