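import numpy as np
import pytest

import emgfusion as ef


@pytest.fixture(scope="session")
def cohort():
    return ef.load_cohort()


@pytest.fixture(scope="session")
def dataset_a(cohort):
    return ef.select_dataset(cohort, "A")


@pytest.fixture(scope="session")
def small_recordings(cohort):
    """Four subjects, both arms, 3 reps/class, mild default paresis."""
    sub = ef.Cohort(cohort.records[:4])
    sim = ef.SimConfig(seed=42, reps_per_class=3, raw_reps_range=(3, 5))
    return ef.simulate_cohort(sub, sim)


@pytest.fixture(scope="session")
def small_segments(small_recordings):
    return ef.fusion.prepare_segments(small_recordings)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
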