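import numpy as np
import pytest

from chromoband import CHR1, Band, BandModel, DEFAULT_BANDS


@pytest.fixture(scope="session")
def spec():
    return CHR1


@pytest.fixture(scope="session")
def five_band_model():
    return DEFAULT_BANDS


@pytest.fixture(scope="session")
def single_band_model():
    return BandModel(bands=(Band(60.0, 10.0, 1.0),), baseline=0.0, centromere_gap=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
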