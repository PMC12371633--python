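import numpy as np
import pytest

from sedcm.cmc import build_jacobian, predict_spectrum
from sedcm.inversion import default_prior
from sedcm.parameters import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def prior():
    return default_prior()


@pytest.fixture(scope="session")
def default_spectrum(params):
    return predict_spectrum(params)


@pytest.fixture(scope="session")
def stable_parameter_sets(params):
    """Five random stable parameterizations within +-1 log-unit of defaults.

    Draws are rejected unless comfortably stable (margin > 3/s) so that
    spectral peaks stay wider than the Welch resolution used in tests.
    """
    rng = np.random.default_rng(20240917)
    out = []
    while len(out) < 5:
        devs = {n: float(rng.uniform(-0.4, 0.4)) for n in params.variable_names}
        candidate = params.update(devs)
        ssm = build_jacobian(candidate)
        if ssm.stable and ssm.stability_margin > 3.0:
            out.append(candidate)
    return out


def make_noisy(spec, sd, seed):
    from sedcm.spectra import SpectralData

    rng = np.random.default_rng(seed)
    return SpectralData(spec.freqs, spec.values * np.exp(rng.normal(0, sd, spec.values.size)))
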