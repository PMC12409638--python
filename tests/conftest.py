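import numpy as np
import pytest

from ramanpat.spectra import Spectrum, SpectrumSet, WavenumberAxis
from ramanpat.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def full_axis() -> WavenumberAxis:
    return WavenumberAxis.full()


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_spectrum(intensities, axis=None, **kwargs) -> Spectrum:
    intensities = np.asarray(intensities, dtype=float)
    if axis is None:
        axis = WavenumberAxis(200.0 + np.arange(intensities.size))
    return Spectrum(axis, intensities, **kwargs)


def make_set(matrix, axis=None, reference=None, **kwargs) -> SpectrumSet:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if axis is None:
        axis = WavenumberAxis(200.0 + np.arange(matrix.shape[1]))
    return SpectrumSet([Spectrum(axis, row, sample_id=f"s{i}", **kwargs)
                        for i, row in enumerate(matrix)], reference=reference)
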