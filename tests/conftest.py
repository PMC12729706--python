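import numpy as np
import pytest

from hdseizure.signal_model import Recording, SeizureAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_recording(rng):
    """2-channel, 2 s @ 512 Hz recording with one ictal second."""
    data = rng.standard_normal((2, 1024))
    return Recording(
        data=data,
        fs=512.0,
        annotations=[SeizureAnnotation(1.0, 2.0)],
        patient_id="fixtureP1",
    )
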