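import numpy as np
import pytest

from spheromech import synthetic_data as synth


@pytest.fixture
def clean_curve_spec():
    """Zero-noise curve with a deterministic 40 pN rupture and no peaks."""
    return synth.CurveSpec(noise_sd=0.0, rupture_mean=40.0, rupture_sd=0.0,
                           peak_amplitudes_sd_units=())


@pytest.fixture
def noisy_peak_spec():
    """Curve carrying the two significant peaks plus a sub-threshold decoy."""
    return synth.CurveSpec(peak_amplitudes_sd_units=(2.2, 2.15, 1.0),
                           noise_sd=2.0, n_points=65536)


@pytest.fixture
def spectra_spec():
    return synth.SpectraSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
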