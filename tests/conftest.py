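import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from sersraman.containers import SpectralAxis
from sersraman.preprocess import PreprocessConfig
from sersraman.synthetic import (
    make_default_profiles,
    simulate_raman_dataset,
)


@pytest.fixture(scope="session")
def raman_axis():
    return SpectralAxis.from_range(600.0, 3400.0, 2.0)


@pytest.fixture(scope="session")
def small_axis():
    """Short fingerprint-region axis for fast unit tests."""
    return SpectralAxis.from_range(800.0, 1800.0, 2.0)


@pytest.fixture(scope="session")
def profiles():
    return make_default_profiles()


@pytest.fixture(scope="session")
def small_dataset(profiles, raman_axis):
    """3 classes x 6 cells x 3 spectra — enough structure for chemometrics
    tests at a fraction of the full-study cost."""
    return simulate_raman_dataset(profiles, n_cells=6, spectra_per_cell=3,
                                  axis=raman_axis, rng_seed=42)


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    from sersraman.preprocess import preprocess_pipeline
    return preprocess_pipeline(small_dataset, PreprocessConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
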