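import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lmcsleepnet import synth
from lmcsleepnet.tfr import ScalogramConfig


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three synthetic subjects, 10 epochs each (raw recordings)."""
    return synth.synth_dataset(n_subjects=3, epochs_per_subject=10, seed=11)


@pytest.fixture(scope="session")
def tiny_arrays(tiny_dataset):
    """Preprocessed scalogram arrays for the tiny dataset."""
    return synth.synth_scalogram_arrays(tiny_dataset, ScalogramConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
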