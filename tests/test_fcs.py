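"""Correlator, diffusion-model fit, lifetime MLE, PN interpretation."""
import numpy as np
import pytest

from fluorobind import fcs, synthetic as syn
from fluorobind.exceptions import InsufficientDataError, ValidationError
from fluorobind.types import PhotonStream


def _poisson_stream(rate, duration, seed):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    macro = np.sort(rng.random(n) * duration)
    micro = rng.random(n) * 25.0
    return PhotonStream(macro, micro, {"duration": duration,
                                       "pulse_period_ns": 25.0})


class TestCorrelate:
    def test_constant_rate_stream_uncorrelated(self):
        # a homogeneous Poisson stream has G = 0 beyond shot noise
        stream = _poisson_stream(5e4, 5.0, seed=0)
        curve = fcs.correlate(stream, "multi_tau", bin_width=1e-4, max_lag=0.2)
        n_bin = 5e4 * 1e-4
        se = 1.0 / (n_bin * np.sqrt(5.0 / 1e-4))  # shot-noise scale at lag 1
        assert np.all(np.abs(curve.G) < max(3 * se, 0.005))

    def test_amplitude_reciprocal_particle_number(self, bright_stream):
        params, stream = bright_stream
        curve = fcs.correlate(stream, "multi_tau", bin_width=2e-5, max_lag=0.5)
        fit = fcs.fit_diffusion_model(curve, kappa=params.kappa)
        assert fit.PN == pytest.approx(params.expected_pn, rel=0.10)
        assert fit.tD == pytest.approx(params.diffusion_time, rel=0.10)

    def test_multi_tau_matches_direct_oracle(self, bright_stream):
        # brute-force binned autocorrelation is the reference; deviation
        # is measured against the zero-lag amplitude because both
        # estimators fluctuate around zero in the far tail
        _, stream = bright_stream
        mt = fcs.correlate(stream, "multi_tau", bin_width=2e-5, max_lag=0.2)
        dr = fcs.correlate(stream, "direct", bin_width=2e-5, lags=mt.lags)
        km = np.round(mt.lags / 2e-5).astype(int)
        kd = np.round(dr.lags / 2e-5).astype(int)
        gm = dict(zip(km, mt.G))
        gd = dict(zip(kd, dr.G))
        shared = np.intersect1d(km, kd)
        assert shared.size >= 30
        amplitude = float(np.mean(mt.G[:3]))
        dev = max(abs(gm[k] - gd[k]) for k in shared)
        assert dev <= 0.02 * amplitude

    def test_exact_on_first_cascade(self, bright_stream):
        # before any rebinning the two schemes are the same estimator
        _, stream = bright_stream
        mt = fcs.correlate(stream, "multi_tau", bin_width=2e-5,
                           channels_per_cascade=8, max_lag=0.2)
        dr = fcs.correlate(stream, "direct", bin_width=2e-5,
                           lags=mt.lags[:8])
        np.testing.assert_allclose(mt.G[:8], dr.G, rtol=1e-12)

    def test_empty_stream_rejected(self):
        empty = PhotonStream(np.array([]), np.array([]), {"duration": 1.0})
        with pytest.raises(ValidationError):
            fcs.correlate(empty)

    def test_excessive_lag_truncated_with_warning(self):
        stream = _poisson_stream(1e4, 2.0, seed=1)
        with pytest.warns(UserWarning):
            curve = fcs.correlate(stream, "multi_tau", bin_width=1e-4,
                                  max_lag=1.5)
        assert curve.lags[-1] <= 0.2


class TestDiffusionFit:
    @pytest.mark.parametrize("n_true,td_true", [(5.0, 0.070), (0.7, 0.0035)])
    def test_analytic_round_trip(self, n_true, td_true):
        curve = syn.gen_correlation_curve(n_true, td_true, kappa=5.0)
        fit = fcs.fit_diffusion_model(curve, kappa=5.0)
        assert fit.converged
        assert fit.PN == pytest.approx(n_true, rel=1e-4)
        assert fit.tD == pytest.approx(td_true, rel=1e-4)

    def test_amplitude_and_timescale_separable(self):
        curve = syn.gen_correlation_curve(5.0, 0.070, kappa=5.0)
        halved = type(curve)(curve.lags, curve.G / 2.0)
        fit = fcs.fit_diffusion_model(halved, kappa=5.0)
        assert fit.PN == pytest.approx(10.0, rel=1e-4)
        assert fit.tD == pytest.approx(0.070, rel=1e-4)

    def test_amplitude_identity(self):
        curve = syn.gen_correlation_curve(3.3, 0.01, kappa=5.0)
        fit = fcs.fit_diffusion_model(curve, kappa=5.0)
        assert fit.PN * fit.amplitude == pytest.approx(1.0, rel=1e-12)

    def test_too_few_lags_rejected(self):
        curve = syn.gen_correlation_curve(5.0, 0.07, lags=np.geomspace(1e-4, 1, 5))
        with pytest.raises(InsufficientDataError):
            fcs.fit_diffusion_model(curve)

    def test_stream_level_recovery_over_seeds(self):
        # scaled-down end-to-end: simulate, correlate, fit; both
        # parameters within the 10% reporting tolerance for every seed
        for seed in range(20):
            params = syn.FCSSimParams(
                concentration=2e-9, w0=0.35, kappa=2.0,
                diffusion_coeff=153.125,        # tD = 0.2 ms
                brightness=5e5, duration=2.0, dt=1e-5, seed=seed)
            stream = syn.gen_fcs_photon_stream(params)
            curve = fcs.correlate(stream, "multi_tau", bin_width=1e-5,
                                  max_lag=0.1)
            fit = fcs.fit_diffusion_model(curve, kappa=params.kappa)
            assert fit.tD == pytest.approx(params.diffusion_time, rel=0.10)
            assert fit.PN == pytest.approx(params.expected_pn, rel=0.10)


class TestLifetime:
    @pytest.mark.parametrize("tau", [4.25, 2.3])
    def test_pure_decay_recovery(self, tau):
        times = syn.gen_decay_microtimes(tau, 100_000, seed=12)
        fit = fcs.fit_lifetime(times, pulse_period=25.0)
        assert fit.tau == pytest.approx(tau, abs=0.05)

    def test_heavy_background_tolerated(self):
        # 50% uniform background: estimate within 3 SE of the truth
        reps = [fcs.fit_lifetime(
            syn.gen_decay_microtimes(4.0, 50_000, background_fraction=0.5,
                                     seed=s), pulse_period=25.0).tau
            for s in range(12)]
        reps = np.asarray(reps)
        se = reps.std(ddof=1) / np.sqrt(reps.size)
        assert abs(reps.mean() - 4.0) < 3 * se

    def test_estimator_bias_below_reporting_precision(self):
        errs = [fcs.fit_lifetime(
            syn.gen_decay_microtimes(4.25, 100_000, background_fraction=0.05,
                                     seed=s), pulse_period=25.0).tau - 4.25
            for s in range(30)]
        assert abs(np.mean(errs)) < 0.02

    def test_too_few_photons_rejected(self):
        with pytest.raises(InsufficientDataError):
            fcs.fit_lifetime(syn.gen_decay_microtimes(4.0, 500, seed=0))


class TestParticleNumber:
    def test_calibration_point(self):
        # 1 nM in a w0 = 0.35 µm, kappa = 5 volume: about 0.72 particles
        assert fcs.expected_particle_number(1e-9, 0.35, 5.0) \
            == pytest.approx(0.72, abs=0.01)

    def test_linear_in_concentration(self):
        one = fcs.expected_particle_number(1e-9, 0.35, 5.0)
        two = fcs.expected_particle_number(2e-9, 0.35, 5.0)
        assert two == pytest.approx(2.0 * one)
        assert fcs.expected_particle_number(0.0, 0.35, 5.0) == 0.0

    @pytest.mark.parametrize("pn,expected,label", [
        (0.7, 0.7, "folded"),        # compacted, point-like molecule
        (5.0, 0.7, "relaxed"),       # extended coil, many segments
        (1.2, 0.7, "intermediate"),
    ])
    def test_folding_classification(self, pn, expected, label):
        fit = fcs.FCSFit(PN=pn, tD=0.01, kappa=5.0, offset=0.0,
                         converged=True, amplitude=1.0 / pn)
        assert fcs.classify_folding(fit, expected) == label

    def test_multiple_emitters_inflate_apparent_pn(self):
        # a relaxed plasmid modelled as several labelled segments shows
        # more apparent particles than molecules
        params = syn.FCSSimParams(concentration=1e-9, duration=0.5,
                                  diffusion_coeff=20.0, dt=1e-4,
                                  emitters_per_molecule=7, seed=0)
        assert params.expected_pn == pytest.approx(7 * 0.7183, rel=0.02)
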