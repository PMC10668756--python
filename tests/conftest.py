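import numpy as np
import pytest

from cometkit import classification
from cometkit.synthetic import SynthConfig, generate_assay_image

#: the 30-female storage-time / viability table used across statistics tests
STORAGE_MONTHS = np.array(
    [0, 0, 0, 0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3, 4.6, 5.2, 5.5, 5.5, 5.6,
     9.8, 10.5, 11.0, 11.6, 12.2, 12.3, 12.3, 12.6, 13.2, 14.0]
)
VIABILITY = np.array(
    [100, 100, 99, 98, 97, 96, 98, 96, 31, 99, 96, 83, 81, 55, 8, 30, 62, 44,
     24, 18, 26, 47, 1, 0, 1, 0, 0, 1, 0, 0],
    dtype=float,
)


@pytest.fixture(scope="session")
def default_model():
    """The packaged synthetic-trained decision tree (trained once per run)."""
    return classification.default_model()


@pytest.fixture(scope="session")
def scene42():
    """A fixed 10-comet synthetic scene with ground truth."""
    return generate_assay_image(SynthConfig(seed=42, n_comets=10))


@pytest.fixture()
def single_comet_config():
    return SynthConfig(width=192, height=96, n_comets=1, min_spacing=4.0)
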