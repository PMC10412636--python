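import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bright_stream():
    """A short, bright photon stream shared by the correlator tests.

    2 nM diffusers, tD = 0.5 ms, 10 s: large correlation amplitude and
    enough photons that the correlation estimate is smooth.
    """
    from fluorobind.synthetic import FCSSimParams, gen_fcs_photon_stream

    params = FCSSimParams(concentration=2e-9, w0=0.35, kappa=5.0,
                          diffusion_coeff=61.25, brightness=3e5,
                          duration=10.0, dt=2e-5, seed=3)
    return params, gen_fcs_photon_stream(params)
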