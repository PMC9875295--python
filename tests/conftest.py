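import numpy as np
import pytest

from thznitro.io_formats import SpectraSet
from thznitro.synthetic import SimulationConfig, generate_spectra


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_set():
    """3 samples x 5 frequencies, hand-checkable."""
    return SpectraSet(
        frequencies_thz=[0.1, 0.2, 0.3, 0.4, 0.5],
        power=np.arange(15, dtype=float).reshape(3, 5),
        nitrogen_pct=[1.0, 2.0, 3.0],
        sample_ids=["a", "b", "c"],
        gradient_labels=["g1", "g1", "g2"],
    )


@pytest.fixture(scope="session")
def default_world():
    """One realization of the default synthetic benchmark (80 x 682)."""
    return generate_spectra(SimulationConfig(), seed=7)


@pytest.fixture(scope="session")
def small_world():
    """Scaled-down synthetic world for expensive loops (40 samples, 120 points)."""
    cfg = SimulationConfig(
        samples_per_gradient=10,
        n_frequencies=120,
        informative_bands_thz=(0.4, 0.7, 0.95),
        interferent_bands_thz=(0.2, 0.55, 0.85, 1.2),
    )
    return cfg, generate_spectra(cfg, seed=11)
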