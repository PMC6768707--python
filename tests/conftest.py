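import numpy as np
import pytest

from vbgnsum import VenueSample, generate_population


@pytest.fixture
def toy_sample() -> VenueSample:
    """Two key respondents (v=[2,4], c=[1,2]) and two non-key (y=[1,3], c=[1,1])."""
    return VenueSample(
        person_id=np.arange(4),
        is_key=np.array([True, True, False, False]),
        c=np.array([1.0, 2.0, 1.0, 1.0]),
        y=np.array([0, 0, 1, 3], dtype=np.int64),
        v=np.array([2.0, 4.0, np.nan, np.nan]),
    )


@pytest.fixture(scope="session")
def small_population():
    """A 500-person frame with 50 key members, equal attendance, no error."""
    return generate_population(500, 50, mean_degree_to_key=3.0, seed=42)
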