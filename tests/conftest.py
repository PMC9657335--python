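import numpy as np
import pytest

from emglesion.preprocessing import SegmentDataset, preprocess_recordings
from emglesion.synthetic import LesionRegime, SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_recordings():
    """20 pre + 20 post recordings at the default study conditions."""
    return generate_dataset(20, 20, SimulationConfig(), LesionRegime(), seed=11)


@pytest.fixture(scope="session")
def small_split(small_recordings):
    """(train, test) SegmentDatasets from the small recordings."""
    return preprocess_recordings(small_recordings, seed=11)


@pytest.fixture()
def toy_dataset():
    """Tiny deterministic segment dataset with both classes."""
    rng = np.random.default_rng(5)
    segments = rng.random((20, 50))
    labels = np.array([0] * 8 + [1] * 12)
    return SegmentDataset(segments, labels, 50)
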