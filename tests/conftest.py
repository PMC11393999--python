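import numpy as np
import pytest

from jc1screen.segmentation import SegmentationParams
from jc1screen.synthetic import ArtifactRates, PhantomParams, SimulationTruth

CCCP = (0.5, 5.0, 25.0, 50.0, 250.0, 500.0, 2500.0)


@pytest.fixture
def seg_params():
    return SegmentationParams()


@pytest.fixture
def truth():
    return SimulationTruth(seed=0)


@pytest.fixture
def clean_phantom():
    """Artifact-free phantom with a short stack for fast tests."""
    return PhantomParams(z_levels=3, artifact_rates=ArtifactRates())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
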