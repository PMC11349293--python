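import warnings

import numpy as np
import pytest

from pallidyn.features import SpikeSegment

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def regular_train() -> SpikeSegment:
    """100 Hz perfectly regular train, 10 s."""
    times = np.arange(0.0, 10.0, 0.01)
    return SpikeSegment(times, 10.0, patient_id="p0", segment_id="reg")


@pytest.fixture
def poisson_train() -> SpikeSegment:
    """Homogeneous 60 Hz Poisson train, 60 s, fixed seed."""
    rng = np.random.default_rng(42)
    isis = rng.exponential(1.0 / 60.0, 5000)
    times = np.cumsum(isis)
    times = times[times < 60.0]
    return SpikeSegment(times, 60.0, patient_id="p1", segment_id="poiss")
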