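import warnings

import numpy as np
import pytest

from devsource.data_io import load_montage
from devsource.localize import HeadModel

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning, module="mne")


@pytest.fixture(scope="session")
def head_model() -> HeadModel:
    return HeadModel()


@pytest.fixture(scope="session")
def montage68(head_model):
    return load_montage("standard-68", scalp_radius=head_model.scalp_radius)


@pytest.fixture(scope="session")
def montage32(head_model):
    return load_montage("standard-32", scalp_radius=head_model.scalp_radius)


@pytest.fixture(scope="session")
def montage24(head_model):
    return load_montage("standard-24", scalp_radius=head_model.scalp_radius)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
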