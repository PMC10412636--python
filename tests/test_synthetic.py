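"""Generator correctness: exact noiseless forms, seeding, noise structure."""
import numpy as np
import pytest

from fluorobind import synthetic as syn
from fluorobind.exceptions import ConfigurationError, ValidationError
from fluorobind.membrane import compute_anisotropy


class TestQuenchingTitration:
    def test_stern_volmer_halving(self):
        # K_SV * Q = 1 halves the intensity
        truth = syn.QuenchGroundTruth("stern_volmer", F0=100.0, K_SV=1e4)
        series = syn.gen_quenching_titration(truth, [1e-4], unit="M")
        assert series.F[0] == pytest.approx(50.0)

    def test_power_binding_coincides_with_sv_at_n_1(self):
        q = np.linspace(1e-6, 3e-5, 12)
        sv = syn.gen_quenching_titration(
            syn.QuenchGroundTruth("stern_volmer", K_SV=2e4), q, unit="M")
        pb = syn.gen_quenching_titration(
            syn.QuenchGroundTruth("power_binding", K_b=2e4, n=1.0), q, unit="M")
        np.testing.assert_allclose(sv.F, pb.F, rtol=1e-12)

    def test_partition_inverse_model(self):
        # (F0/F) - 1 must equal lip * Q / (K_d + Q) exactly
        truth = syn.QuenchGroundTruth("partition", F0=80.0, K_d=12.97,
                                      lip_conc=0.1)
        q = np.linspace(1.0, 30.0, 10)
        series = syn.gen_quenching_titration(truth, q)
        lhs = series.F0 / series.F - 1.0
        np.testing.assert_allclose(lhs, 0.1 * q / (12.97 + q), rtol=1e-12)

    def test_seeded_noise_is_bit_reproducible(self):
        truth = syn.QuenchGroundTruth("stern_volmer", K_SV=1e4,
                                      noise_cv=0.05, seed=42)
        q = np.linspace(1e-6, 3e-5, 8)
        a = syn.gen_quenching_titration(truth, q, unit="M")
        b = syn.gen_quenching_titration(truth, q, unit="M")
        np.testing.assert_array_equal(a.F, b.F)

    def test_noise_is_multiplicative_unit_mean(self):
        truth = syn.QuenchGroundTruth("stern_volmer", F0=100.0, K_SV=1e4,
                                      noise_cv=0.10, seed=5)
        series = syn.gen_quenching_titration(
            truth, [1e-4], unit="M", n_replicates=4000)
        ratios = series.F / 50.0
        assert ratios.mean() == pytest.approx(1.0, abs=3 * 0.10 / np.sqrt(4000))
        assert ratios.std() == pytest.approx(0.10, rel=0.1)

    @pytest.mark.parametrize("kwargs", [
        dict(model="stern_volmer"),                       # K_SV unset
        dict(model="partition", K_d=10.0),                # lip_conc unset
        dict(model="nope", K_SV=1.0),                     # unknown model
    ])
    def test_incomplete_configuration_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            syn.QuenchGroundTruth(**kwargs)

    def test_nonpositive_concentration_rejected(self):
        truth = syn.QuenchGroundTruth("stern_volmer", K_SV=1e4)
        with pytest.raises(ValidationError):
            syn.gen_quenching_titration(truth, [0.0, 1e-5], unit="M")


class TestPolarizedReadings:
    def test_isotropic_case(self):
        (r,) = syn.gen_polarized_readings(0.0, total_I=3.0, G=1.0)
        assert r.I_par == pytest.approx(1.0)
        assert r.I_perp == pytest.approx(1.0)

    @pytest.mark.parametrize("true_a", [-0.2, 0.0, 0.13, 0.4, 0.95])
    def test_noiseless_round_trip(self, true_a):
        (r,) = syn.gen_polarized_readings(true_a, total_I=7.0, G=1.2)
        assert compute_anisotropy(r) == pytest.approx(true_a, abs=1e-12)
        assert r.I_par + 2 * r.G * r.I_perp == pytest.approx(7.0)

    def test_noisy_mean_recovers_truth(self):
        # Monte Carlo across seeds: mean recovered anisotropy within 3 SE
        values = []
        for seed in range(1000):
            for r in syn.gen_polarized_readings(0.13, G=1.2, noise_cv=0.02,
                                                n_replicates=10, seed=seed):
                values.append(compute_anisotropy(r))
        values = np.asarray(values)
        se = values.std(ddof=1) / np.sqrt(values.size)
        assert abs(values.mean() - 0.13) < 3 * se

    def test_out_of_range_anisotropy_rejected(self):
        with pytest.raises(ValidationError):
            syn.gen_polarized_readings(1.2)


class TestPhotonStream:
    def test_dark_sample_gives_empty_stream(self):
        params = syn.FCSSimParams(concentration=1e-9, brightness=0.0,
                                  background_rate=0.0, duration=0.5,
                                  diffusion_coeff=20.0, dt=1e-4, seed=0)
        stream = syn.gen_fcs_photon_stream(params)
        assert len(stream) == 0

    def test_expected_pn_closed_form(self):
        # 1 nM, w0 = 0.35 µm, kappa = 5 -> about 0.72 particles
        params = syn.FCSSimParams(concentration=1e-9, w0=0.35, kappa=5.0,
                                  duration=0.5, diffusion_coeff=20.0,
                                  dt=1e-4, seed=0)
        assert params.expected_pn == pytest.approx(0.72, abs=0.01)

    def test_mean_count_rate_matches_profile_average(self, bright_stream):
        # rate = brightness * <profile over box> * n_particles + background
        params, stream = bright_stream
        box = np.asarray(params.box_side)
        mean_profile = ((np.pi / 2.0) ** 1.5 * params.w0 ** 2
                        * params.kappa * params.w0 / np.prod(box))
        expected = params.brightness * mean_profile * params.n_particles
        edges = np.linspace(0.0, params.duration, 21)
        block_rates = np.histogram(stream.macro_times, bins=edges)[0] \
            / np.diff(edges)
        se = block_rates.std(ddof=1) / np.sqrt(block_rates.size)
        assert abs(block_rates.mean() - expected) < 3 * se

    def test_stream_is_time_ordered_and_reproducible(self):
        params = syn.FCSSimParams(concentration=5e-9, duration=0.5,
                                  brightness=2e4, background_rate=500.0,
                                  diffusion_coeff=30.625, dt=5e-5, seed=11)
        a = syn.gen_fcs_photon_stream(params)
        b = syn.gen_fcs_photon_stream(params)
        assert np.all(np.diff(a.macro_times) >= 0)
        np.testing.assert_array_equal(a.macro_times, b.macro_times)
        np.testing.assert_array_equal(a.micro_times, b.micro_times)
        assert a.micro_times.min() >= 0
        assert a.micro_times.max() < params.pulse_period_ns

    def test_bad_dt_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.FCSSimParams(concentration=1e-9, diffusion_coeff=1000.0,
                             dt=1e-3, duration=10.0)


class TestCorrelationCurve:
    def test_small_lag_amplitude_is_reciprocal_n(self):
        curve = syn.gen_correlation_curve(5.0, 0.07, kappa=5.0,
                                          lags=np.geomspace(7e-8, 7.0, 100))
        assert curve.G[0] == pytest.approx(1.0 / 5.0, rel=1e-5)

    def test_half_amplitude_at_td_in_2d_limit(self):
        # kappa -> infinity removes the axial factor
        curve = syn.gen_correlation_curve(4.0, 0.01, kappa=1e6,
                                          lags=np.array([0.01]))
        assert curve.G[0] == pytest.approx(1.0 / 8.0, rel=1e-6)

    def test_noise_is_seeded(self):
        a = syn.gen_correlation_curve(5.0, 0.07, noise_sd=0.01, seed=3)
        b = syn.gen_correlation_curve(5.0, 0.07, noise_sd=0.01, seed=3)
        np.testing.assert_array_equal(a.G, b.G)


class TestFTIRSpectrum:
    def test_reproducible_and_additive(self):
        bands = [syn.BandSpec(971.32, 10.0, 1.0),
                 syn.BandSpec(985.0, 6.0, 0.5, shape="lorentzian")]
        a = syn.gen_ftir_spectrum(bands, (940, 1000, 0.5), baseline=(0.1,),
                                  noise_sd=0.01, seed=9)
        b = syn.gen_ftir_spectrum(bands, (940, 1000, 0.5), baseline=(0.1,),
                                  noise_sd=0.01, seed=9)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_band_shapes_peak_at_center_height(self):
        for shape in ("gaussian", "lorentzian", "pseudo_voigt"):
            band = syn.BandSpec(1000.0, 8.0, 2.0, shape=shape)
            x = np.array([996.0, 1000.0, 1004.0])
            y = band.profile(x)
            assert y[1] == pytest.approx(2.0)
            assert y[0] == pytest.approx(1.0, rel=1e-9)  # FWHM definition

    def test_empty_band_list_rejected(self):
        with pytest.raises(ValidationError):
            syn.gen_ftir_spectrum([], (940, 1000, 0.5))

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValidationError):
            syn.gen_ftir_spectrum([syn.BandSpec(2000.0, 5.0, 1.0)],
                                  (940, 1000, 0.5))
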