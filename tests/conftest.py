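import numpy as np
import pytest

from seizcos.io import Recording, SeizureInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_recording(rng):
    """20 s, 3-channel, 64 Hz recording with two annotated intervals."""
    data = rng.normal(0, 10, size=(3, 20 * 64))
    return Recording(
        ["C1", "C2", "C3"], 64.0, data,
        [SeizureInterval(4.0, 6.0), SeizureInterval(12.5, 14.0)],
    )
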