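"""Synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here: quenching
titrations (Stern-Volmer, power-law binding, membrane partition),
polarized intensity pairs at a set anisotropy, photon streams from a
Brownian-dynamics simulation of fluorophores crossing a 3D Gaussian
confocal volume, analytic FCS correlation curves, TCSPC micro-time
samples, and baseline-plus-band infrared spectra.

Noise conventions: fluorescence intensities receive multiplicative
lognormal noise parameterised by a coefficient of variation (keeps
intensities positive, matches detector behaviour); analytic correlation
curves receive additive Gaussian noise; photon streams are exactly
Poissonian by construction.  All generators are deterministic under a
seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, ValidationError
from .types import CorrelationCurve, PhotonStream, PolarizedReading, Spectrum, TitrationSeries

AVOGADRO = 6.02214076e23  # 1/mol


# ---------------------------------------------------------------------------
# quenching titrations
# ---------------------------------------------------------------------------

@dataclass
class QuenchGroundTruth:
    """Ground-truth parameters for one synthetic quenching titration.

    ``model`` selects which parameters are required:

    - ``stern_volmer``: F = F0 / (1 + K_SV [Q]) needs ``K_SV`` (1/M).
    - ``power_binding``: F = F0 / (1 + K_b [Q]^n) needs ``K_b`` (M^-n)
      and ``n``.
    - ``partition``: (F0/F) - 1 = lip_conc [Q] / (K_d + [Q]) needs
      ``K_d`` (same unit as the concentration grid, conventionally µM)
      and ``lip_conc`` (mg/mL, acts as a dimensionless scale that
      cancels in the downstream slope/intercept ratio).
    """

    model: str
    F0: float = 100.0
    K_SV: float | None = None
    K_b: float | None = None
    n: float | None = None
    K_d: float | None = None
    lip_conc: float | None = None
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.F0 <= 0:
            raise ValidationError("F0 must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be nonnegative")
        required = {
            "stern_volmer": ("K_SV",),
            "power_binding": ("K_b", "n"),
            "partition": ("K_d", "lip_conc"),
        }
        if self.model not in required:
            raise ConfigurationError(f"unknown quenching model {self.model!r}")
        for name in required[self.model]:
            value = getattr(self, name)
            if value is None or value <= 0:
                raise ConfigurationError(
                    f"model {self.model!r} requires positive {name}")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def gen_quenching_titration(truth: QuenchGroundTruth, concentrations,
                            unit: str = "uM",
                            n_replicates: int = 1) -> TitrationSeries:
    """Generate a quenching titration from ground-truth parameters.

    ``concentrations`` must be strictly positive and ascending, in the
    unit the model parameters assume (molar for ``stern_volmer`` and
    ``power_binding`` constants quoted in 1/M; the partition model is
    unit-agnostic as long as K_d shares the grid's unit).  ``unit`` is
    the tag recorded on the returned series.
    """
    q = np.asarray(concentrations, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValidationError("concentrations must be a nonempty 1-D sequence")
    if np.any(q <= 0):
        raise ValidationError("concentrations must be strictly positive")
    if np.any(np.diff(q) <= 0):
        raise ValidationError("concentrations must be sorted ascending")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")

    if truth.model == "stern_volmer":
        f = truth.F0 / (1.0 + truth.K_SV * q)
    elif truth.model == "power_binding":
        f = truth.F0 / (1.0 + truth.K_b * np.power(q, truth.n))
    else:  # partition: (F0/F) - 1 = lip * q / (K_d + q)
        f = truth.F0 / (1.0 + truth.lip_conc * q / (truth.K_d + q))

    q_all = np.tile(q, n_replicates)
    f_all = np.tile(f, n_replicates)
    rep = np.repeat(np.arange(n_replicates), q.size) if n_replicates > 1 else None
    if truth.noise_cv > 0:
        rng = np.random.default_rng(truth.seed)
        f_all = f_all * _lognormal_factor(rng, truth.noise_cv, f_all.shape)
    return TitrationSeries(q_all, f_all, truth.F0, unit=unit,
                           replicate_id=rep, lip_conc=truth.lip_conc)


# ---------------------------------------------------------------------------
# polarized readings
# ---------------------------------------------------------------------------

def gen_polarized_readings(true_A: float, total_I: float = 3.0, G: float = 1.0,
                           noise_cv: float = 0.0, n_replicates: int = 1,
                           seed: int = 0) -> list[PolarizedReading]:
    """Generate polarized intensity pairs consistent with an anisotropy.

    Noiseless readings satisfy A = (I_par - G I_perp)/(I_par + 2 G I_perp)
    exactly, with the total I_par + 2 G I_perp equal to ``total_I``.
    Multiplicative lognormal noise (CV ``noise_cv``) is applied to each
    intensity channel independently.
    """
    if not (-0.5 <= true_A <= 1.0):
        raise ValidationError("anisotropy must lie in [-0.5, 1.0]")
    if total_I <= 0 or G <= 0:
        raise ValidationError("total_I and G must be positive")
    i_par = total_I * (1.0 + 2.0 * true_A) / 3.0
    i_perp = total_I * (1.0 - true_A) / (3.0 * G)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        if noise_cv > 0:
            fpar, fperp = _lognormal_factor(rng, noise_cv, 2)
        else:
            fpar = fperp = 1.0
        out.append(PolarizedReading(i_par * fpar, i_perp * fperp, G))
    return out


# ---------------------------------------------------------------------------
# FCS photon-stream simulation
# ---------------------------------------------------------------------------

@dataclass
class FCSSimParams:
    """Parameters of the Brownian-dynamics photon-stream simulation.

    The detection profile is a 3D Gaussian,
    ``exp(-2 r^2/w0^2 - 2 z^2/(kappa w0)^2)``, centred in a periodic box.
    ``box_side`` may be a single side length (cubic box) or an (x, y, z)
    triple; the default box is (10 w0, 10 w0, 10 kappa w0) so the beam
    never feels the boundary.  Ground truths implied by the parameters:
    ``tD = w0^2 / (4 D)`` and
    ``PN = concentration * N_A * pi^{3/2} w0^2 (kappa w0)``.

    ``emitters_per_molecule`` > 1 models an extended, multiply-labelled
    molecule (e.g. a relaxed plasmid carrying many intercalated dyes) as
    that many independent point emitters, which inflates the apparent
    particle number above the molecular concentration value.
    """

    concentration: float          # molar
    w0: float = 0.35              # µm, lateral 1/e^2 radius
    kappa: float = 5.0            # axial/lateral structure parameter
    diffusion_coeff: float = 30.625  # µm^2/s (tD = 1 ms at w0 = 0.35)
    brightness: float = 1e5      # photons/s at beam centre, per emitter
    lifetime_ns: float = 4.25     # ns
    background_rate: float = 0.0  # photons/s
    duration: float = 60.0        # s
    dt: float = 5e-5              # s, propagation step
    box_side: float | tuple[float, float, float] | None = None
    pulse_period_ns: float = 25.0
    irf_offset_ns: float = 0.0
    emitters_per_molecule: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("concentration", "w0", "kappa", "diffusion_coeff",
                     "duration", "dt", "pulse_period_ns"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.brightness < 0 or self.background_rate < 0:
            raise ConfigurationError("rates must be nonnegative")
        if self.emitters_per_molecule < 1:
            raise ConfigurationError("emitters_per_molecule must be >= 1")
        if self.box_side is None:
            self.box_side = (10.0 * self.w0, 10.0 * self.w0,
                             10.0 * self.kappa * self.w0)
        elif np.isscalar(self.box_side):
            self.box_side = (float(self.box_side),) * 3
        box = np.asarray(self.box_side, float)
        if box.shape != (3,) or np.any(box <= 0):
            raise ConfigurationError("box_side must be a scalar or 3 positive sides")
        if box.min() < 10.0 * self.w0:
            raise ConfigurationError("every box side must be >= 10 w0")
        step = np.sqrt(2.0 * self.diffusion_coeff * self.dt)
        if step > self.w0 / 5.0:
            raise ConfigurationError(
                "dt too large: rms step per axis must be <= w0/5")
        if self.duration < 100.0 * self.diffusion_time:
            raise ConfigurationError("duration must cover >= 100 diffusion times")

    @property
    def diffusion_time(self) -> float:
        """Expected lateral diffusion time tD = w0^2 / (4 D), seconds."""
        return self.w0 ** 2 / (4.0 * self.diffusion_coeff)

    @property
    def box_volume_um3(self) -> float:
        return float(np.prod(self.box_side))

    @property
    def n_particles(self) -> int:
        """Emitters placed in the box (nearest integer to c N_A V_box)."""
        per_molecule = self.emitters_per_molecule
        n_mol = self.concentration * AVOGADRO * self.box_volume_um3 * 1e-15
        return max(1, round(n_mol * per_molecule))

    @property
    def expected_pn(self) -> float:
        """Ground-truth particle number in the effective volume."""
        dens = self.n_particles / self.box_volume_um3
        v_eff = np.pi ** 1.5 * self.w0 ** 2 * (self.kappa * self.w0)
        return dens * v_eff


def gen_fcs_photon_stream(params: FCSSimParams) -> PhotonStream:
    """Simulate a photon stream from diffusing emitters in a confocal spot.

    Emitters perform Brownian steps in a periodic box; per step the
    photon count of each emitter is Poisson with mean
    ``brightness * dt * exp(-2 r^2/w0^2 - 2 z^2/(kappa w0)^2)``.  Signal
    photons carry micro-times ``irf_offset + Exp(lifetime)`` wrapped into
    the pulse period; background photons carry uniform micro-times.
    Photon macro-times are jittered uniformly inside their step so the
    stream has sub-step resolution; the stream is returned time-ordered.
    """
    rng = np.random.default_rng(params.seed)
    box = np.asarray(params.box_side, float)
    n_steps = int(round(params.duration / params.dt))
    n_part = params.n_particles
    sigma = np.sqrt(2.0 * params.diffusion_coeff * params.dt)
    w0sq = params.w0 ** 2
    z0sq = (params.kappa * params.w0) ** 2

    pos = (rng.random((n_part, 3)) - 0.5) * box  # beam centre at origin
    macro_chunks: list[np.ndarray] = []
    n_signal = 0

    # chunk the time axis so per-chunk arrays stay ~tens of MB
    chunk = max(1000, int(2e7 / (3 * n_part)))
    mean_rate = params.brightness * params.dt
    for start in range(0, n_steps, chunk):
        m = min(chunk, n_steps - start)
        steps = rng.normal(0.0, sigma, size=(m, n_part, 3))
        traj = pos[None, :, :] + np.cumsum(steps, axis=0)
        # periodic wrap to [-L/2, L/2)
        traj = (traj + box / 2.0) % box - box / 2.0
        pos = traj[-1]
        if params.brightness > 0:
            expo = (traj[:, :, 0] ** 2 + traj[:, :, 1] ** 2) / w0sq \
                + traj[:, :, 2] ** 2 / z0sq
            counts = rng.poisson(mean_rate * np.exp(-2.0 * expo))
            per_step = counts.sum(axis=1)
            idx = np.nonzero(per_step)[0]
            if idx.size:
                times = (start + np.repeat(idx, per_step[idx])
                         + rng.random(int(per_step[idx].sum()))) * params.dt
                macro_chunks.append(times)
                n_signal += times.size

    if macro_chunks:
        macro_sig = np.concatenate(macro_chunks)
    else:
        macro_sig = np.empty(0)

    # background photons, homogeneous Poisson over the full duration
    n_bg = rng.poisson(params.background_rate * params.duration)
    macro_bg = rng.random(n_bg) * params.duration

    period = params.pulse_period_ns
    micro_sig = (params.irf_offset_ns
                 + rng.exponential(params.lifetime_ns, n_signal)) % period
    micro_bg = rng.random(n_bg) * period

    macro = np.concatenate([macro_sig, macro_bg])
    micro = np.concatenate([micro_sig, micro_bg])
    order = np.argsort(macro, kind="stable")
    meta = {
        "duration": params.duration,
        "pulse_period_ns": period,
        "n_particles": n_part,
        "expected_pn": params.expected_pn,
        "diffusion_time_s": params.diffusion_time,
    }
    return PhotonStream(macro[order], micro[order], meta)


def gen_decay_microtimes(tau_ns: float, n: int, pulse_period_ns: float = 25.0,
                         background_fraction: float = 0.0,
                         offset_ns: float = 0.0, seed: int = 0) -> np.ndarray:
    """Draw TCSPC micro-times: wrapped exponential decay plus uniform background.

    ``background_fraction`` of the ``n`` photons are uniform on the pulse
    period; the rest follow ``offset + Exp(tau)`` wrapped into the period.
    """
    if tau_ns <= 0 or pulse_period_ns <= 0:
        raise ValidationError("tau and pulse period must be positive")
    if not 0.0 <= background_fraction < 1.0:
        raise ValidationError("background_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_bg = rng.binomial(n, background_fraction)
    sig = (offset_ns + rng.exponential(tau_ns, n - n_bg)) % pulse_period_ns
    bg = rng.random(n_bg) * pulse_period_ns
    out = np.concatenate([sig, bg])
    rng.shuffle(out)
    return out


def gen_correlation_curve(N: float, tD: float, kappa: float = 5.0,
                          lags=None, noise_sd: float = 0.0,
                          seed: int = 0) -> CorrelationCurve:
    """Analytic one-component 3D-diffusion correlation curve.

    G(tau) = (1/N) (1 + tau/tD)^-1 (1 + tau/(kappa^2 tD))^-1/2, plus
    additive Gaussian noise of standard deviation ``noise_sd``.  Default
    lags are 200 log-spaced points from tD/1000 to 1000 tD.
    """
    if N <= 0 or tD <= 0 or kappa <= 0:
        raise ValidationError("N, tD and kappa must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    if lags is None:
        lags = np.geomspace(tD / 1000.0, tD * 1000.0, 200)
    lags = np.asarray(lags, dtype=float)
    if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
        raise ValidationError("lags must be positive and strictly increasing")
    g = diffusion_autocorrelation(lags, N, tD, kappa)
    if noise_sd > 0:
        g = g + np.random.default_rng(seed).normal(0.0, noise_sd, g.shape)
    return CorrelationCurve(lags, g)


def diffusion_autocorrelation(tau, N: float, tD: float,
                              kappa: float) -> np.ndarray:
    """One-component 3D Gaussian-volume diffusion model G(tau)."""
    tau = np.asarray(tau, dtype=float)
    return (1.0 / N) / ((1.0 + tau / tD)
                        * np.sqrt(1.0 + tau / (kappa ** 2 * tD)))


# ---------------------------------------------------------------------------
# infrared spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: centre (cm^-1), FWHM, height and line shape."""

    center: float
    fwhm: float
    height: float
    shape: str = "gaussian"
    eta: float = 0.5  # pseudo-Voigt Lorentzian fraction

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValidationError("fwhm must be positive")
        if self.height <= 0:
            raise ValidationError("height must be positive")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValidationError(f"unknown band shape {self.shape!r}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValidationError("eta must lie in [0, 1]")

    def profile(self, x: np.ndarray) -> np.ndarray:
        d = x - self.center
        gauss = np.exp(-4.0 * np.log(2.0) * d * d / (self.fwhm ** 2))
        lorentz = 1.0 / (1.0 + 4.0 * d * d / (self.fwhm ** 2))
        if self.shape == "gaussian":
            y = gauss
        elif self.shape == "lorentzian":
            y = lorentz
        else:
            y = self.eta * lorentz + (1.0 - self.eta) * gauss
        return self.height * y


def gen_ftir_spectrum(bands: list[BandSpec], grid: tuple[float, float, float],
                      baseline=(0.0,), noise_sd: float = 0.0,
                      seed: int = 0, label: str = "") -> Spectrum:
    """Generate a baseline-plus-bands infrared spectrum on a uniform grid.

    ``grid`` is (start, stop, step) in cm^-1; ``baseline`` holds
    polynomial coefficients in ascending order (numpy.polynomial
    convention).  Every band centre must lie inside the grid.
    """
    if not bands:
        raise ValidationError("at least one band is required")
    start, stop, step = grid
    if step <= 0 or stop <= start:
        raise ValidationError("grid must satisfy start < stop, step > 0")
    x = np.arange(start, stop + step / 2.0, step)
    for b in bands:
        if not (start <= b.center <= stop):
            raise ValidationError(f"band at {b.center} cm^-1 outside grid")
    y = np.polynomial.polynomial.polyval(x, np.asarray(baseline, float))
    for b in bands:
        y = y + b.profile(x)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, x.shape)
    return Spectrum(x, y, label=label)
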