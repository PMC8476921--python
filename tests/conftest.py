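import numpy as np
import pytest

from flimspec import PhantomScene, RegionParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_region_scene():
    """64x64 phantom: left half pure autofluorescence at 1.6 ns, right half a
    PpIX-rich mixture reaching 13 ns apparent lifetime."""
    from flimspec import alpha_for_apparent_lifetime

    labels = np.zeros((64, 64), dtype=int)
    labels[:, 32:] = 1
    alpha_hot = alpha_for_apparent_lifetime(13.0)
    return PhantomScene(
        label_map=labels,
        region_params={
            0: RegionParams(alpha_ppix=0.0, tau_auto_ns=1.6, intensity_mv=100.0),
            1: RegionParams(alpha_ppix=alpha_hot, tau_auto_ns=1.6, intensity_mv=100.0),
        },
    )


def quintic(x):
    """A fixed degree-5 curve spanning the lifetime range, used as ground
    truth in fitting tests."""
    return 1.5 + 2.0 * x - 4.0 * x**2 + 30.0 * x**3 - 40.0 * x**4 + 25.0 * x**5


@pytest.fixture
def quintic_truth():
    return quintic
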