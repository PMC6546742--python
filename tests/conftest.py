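import numpy as np
import pytest

from photokin import GeneratorConfig, IRFModel
from photokin.presets import cascade_irf, cascade_sads, cascade_scheme, cascade_ta


@pytest.fixture(scope="session")
def wavelengths():
    return np.linspace(420, 700, 64)


@pytest.fixture(scope="session")
def scheme():
    return cascade_scheme()


@pytest.fixture(scope="session")
def irf():
    return cascade_irf()


@pytest.fixture(scope="session")
def sads(wavelengths):
    return cascade_sads(wavelengths)


@pytest.fixture(scope="session")
def ta_clean():
    return cascade_ta(seed=0, noise_frac=0.0)


@pytest.fixture(scope="session")
def ta_noisy():
    return cascade_ta(seed=0, noise_frac=0.005)


def make_cfg(seed=0, noise_sd=0.0, time_grid=None, time_unit="s", wavelength_grid=None):
    return GeneratorConfig(
        seed=seed,
        noise_sd=noise_sd,
        time_grid=time_grid,
        time_unit=time_unit,
        wavelength_grid=wavelength_grid,
    )
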