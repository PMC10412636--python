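# fluorobind

Quantitative analysis of ligand–membrane, ligand–protein and ligand–DNA
interactions from fluorescence and infrared measurements, built for
flavonoid/anthocyanin-style small-molecule interaction studies. The
package covers the full quantitative chain of such a study:

- **Membrane probes** — steady-state anisotropy
  `A = (I∥ − G·I⊥)/(I∥ + 2G·I⊥)` of bilayer probes (DPH, TMA-DPH),
  percent intensity/anisotropy changes vs control, and the
  ligand–membrane dissociation constant from probe-quenching titrations
  via the double-reciprocal regression
  `1/((F0/F) − 1) = (K_d/L)·(1/[Q]) + 1/L`, with `K_d = slope/intercept`.
- **Protein quenching (HSA)** — inner-filter correction
  `F_corr = F_obs·10^((A_ex+A_em)/2)`, Stern–Volmer constants
  `F0/F = 1 + K_SV[Q]` (with `K_q = K_SV/τ0`), and double-log binding
  parameters `log10[(F0−F)/F] = log10 K_b + n·log10[Q]`.
- **Single-molecule FCS** — a Brownian-dynamics photon-stream simulator
  (3D Gaussian detection volume, TCSPC micro-times), multi-tau and
  brute-force autocorrelators, the one-component 3D diffusion fit
  `G(τ) = (1/N)(1+τ/t_D)⁻¹(1+τ/(κ²t_D))^(−1/2)`, a tail-fit
  maximum-likelihood lifetime estimator, and particle-number-based
  classification of DNA compaction (`PN → c·N_A·π^{3/2}w0²κw0` when a
  plasmid folds into a point-like particle).
- **ATR-FTIR** — band-peak extraction in lipid marker windows
  (choline, phosphate, carbonyl, methylene), subband splitting, and
  peak shifts vs a control spectrum.
- **Statistics** — one-way ANOVA and Duncan's multiple range test with
  a letter display and control-vs-treatment significance flags.

Every analysis has a matching synthetic-data generator with known
ground truth (`fluorobind.synthetic`), so the whole pipeline is testable
without instrument data.

## Worked example

```python
import numpy as np
from fluorobind import synthetic as syn, membrane, protein, fcs

# membrane partition constant: generate a noiseless titration at a known
# K_d and refit it
truth = syn.QuenchGroundTruth("partition", K_d=12.97, lip_conc=0.1)
series = syn.gen_quenching_titration(truth, np.linspace(1, 30, 15))
fit = membrane.fit_partition(series)
print(f"K_d = {fit.K_d:.2f} uM (r^2 = {fit.r_squared:.4f})")

# HSA binding parameters from a double-log fit
hsa = syn.gen_quenching_titration(
    syn.QuenchGroundTruth("power_binding", K_b=96.33e3, n=1.12),
    np.linspace(5e-6, 30e-6, 12), unit="M")
bind = protein.fit_binding_double_log(hsa)
print(f"K_b = {bind.K_b/1e3:.2f}e3 1/M, n = {bind.n:.2f}")

# FCS: simulate 1 nM diffusers for 60 s, correlate, fit
params = syn.FCSSimParams(concentration=1e-9, w0=0.35, kappa=5.0,
                          diffusion_coeff=30.625, brightness=1e5,
                          duration=60.0, dt=5e-5, seed=7)
stream = syn.gen_fcs_photon_stream(params)
curve = fcs.correlate(stream, "multi_tau", bin_width=5e-5, max_lag=2.0)
dfit = fcs.fit_diffusion_model(curve, kappa=5.0)
print(f"PN = {dfit.PN:.2f}, tD = {dfit.tD*1e3:.2f} ms "
      f"(expected {params.expected_pn:.2f}, {params.diffusion_time*1e3:.1f} ms)")
```

prints

```
K_d = 12.97 uM (r^2 = 1.0000)
K_b = 96.33e3 1/M, n = 1.12
PN = 0.72, tD = 1.05 ms (expected 0.72, 1.0 ms)
```

The partition and binding fits recover their generating constants
exactly on noiseless data (the transforms are linear in the fitted
parameters); the stream-level FCS estimate carries the statistical
uncertainty of a 60 s single-molecule measurement — a particle number
within ±0.1 and a diffusion time within ±10%, the reporting precision
customary for these observables.

A command-line interface mirrors the library:
`fluorobind simulate {titration|polarized|fcs|ftir}`,
`fluorobind kd`, `fluorobind hsa`, `fluorobind fcs correlate|fit|lifetime`,
`fluorobind ftir peaks|shifts`, `fluorobind stats`.

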