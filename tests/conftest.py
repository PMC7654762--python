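import numpy as np
import pytest

from pacbox.core import make_bands
from pacbox.signals import SimSpec, simulate_pac_tort


@pytest.fixture(scope="session")
def tort_signal():
    """Benchmark condition: 20 epochs, 10<->100 Hz coupling, sf 512 Hz."""
    return simulate_pac_tort(SimSpec(seed=0))


@pytest.fixture(scope="session")
def small_tort_signal():
    """A faster, smaller coupled signal for unit-level checks."""
    return simulate_pac_tort(
        SimSpec(sf=256, n_epochs=5, n_times=1536, f_pha=10, f_amp=80,
                coupling=0.9, noise=0.5, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_grids():
    return (
        make_bands(2, 20, 2, role="phase"),
        make_bands(60, 160, 10, role="amplitude"),
    )
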