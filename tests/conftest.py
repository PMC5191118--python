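import numpy as np
import pytest

from sparsepose.database import build_database
from sparsepose.skeleton import Skeleton
from sparsepose.synthetic import MotionGeneratorSpec, generate_database


def random_unit_quaternions(rng, *shape):
    q = rng.standard_normal(shape + (4,))
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


@pytest.fixture(scope="session")
def skeleton():
    return Skeleton()


@pytest.fixture(scope="session")
def small_spec():
    # 3 subjects x 3 trials x 600 frames -> 540 database poses
    return MotionGeneratorSpec(n_subjects=3, frames_per_trial=600, seed=7)


@pytest.fixture(scope="session")
def raw_small(small_spec):
    return generate_database(small_spec)


@pytest.fixture(scope="session")
def db_small(raw_small):
    return build_database(raw_small)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
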