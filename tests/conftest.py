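import numpy as np
import pytest

from ratemix import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_landscape():
    """A small heterogeneous-gene-flow landscape shared by pipeline tests."""
    return simulate.simulate_im_landscape(
        seed=101,
        classes=[
            {"fst": 0.15, "n_windows": 8},
            {"fst": 0.45, "n_windows": 8},
            {"fst": 0.75, "n_windows": 8},
        ],
        N=150.0,
        mu1=2.5e-3,
        mu2=2.5e-3 * 1.8,
        n_per_pop=3,
        loci_per_window=10,
    )
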