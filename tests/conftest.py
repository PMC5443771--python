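import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from septfc.matching_pursuit import DictionaryConfig, build_dictionary
from septfc.recording import SEPRecording


#: small sample grid for pursuit tests: 256 samples at 2 kHz (128 ms epoch),
#: dictionary ~3k atoms so exhaustive oracles stay fast
SMALL_N = 256
SMALL_FS = 2000.0


@pytest.fixture(scope="session")
def small_dictionary():
    return build_dictionary(SMALL_N, SMALL_FS)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture()
def noise_recording(rng):
    return SEPRecording(rng.normal(0, 1.0, SMALL_N), SMALL_FS, bandpass=(10.0, 900.0))


def make_recording(samples, fs=SMALL_FS, **kw):
    return SEPRecording(np.asarray(samples, dtype=float), fs, **kw)
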