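import numpy as np
import pytest

import proteospike as ps


@pytest.fixture(scope="session")
def table() -> ps.ProfileTable:
    return ps.load_profile_table()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)


def make_recording(values, dt=1.0, **kwargs) -> ps.Recording:
    values = np.asarray(values, float)
    return ps.Recording(np.arange(len(values)) * dt, values, **kwargs)
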