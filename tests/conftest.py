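import numpy as np
import pytest

from actibrain.preprocess import preprocess_records
from actibrain.synthetic import gen_activity_records, gen_subject_traits


@pytest.fixture(scope="session")
def small_traits():
    return gen_subject_traits(12, 3, seed=11)


@pytest.fixture(scope="session")
def small_records(small_traits):
    return gen_activity_records(
        small_traits, days_per_subject=4, missing_run_prob=0.15, seed=12
    )


@pytest.fixture(scope="session")
def small_segments(small_records):
    segments, _ = preprocess_records(small_records)
    return segments


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
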