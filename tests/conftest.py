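import numpy as np
import pytest
from hypothesis import settings

from madvar_select import FeatureMatrix, ScoreVector

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    """5 features x 4 samples: 4 constant rows, 1 alternating row."""
    values = np.array([
        [1.0, 1.0, 1.0, 1.0],
        [2.0, 2.0, 2.0, 2.0],
        [3.0, 3.0, 3.0, 3.0],
        [4.0, 4.0, 4.0, 4.0],
        [0.0, 10.0, 0.0, 10.0],
    ])
    return FeatureMatrix(values, ["g1", "g2", "g3", "g4", "g5"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def random_matrix(rng):
    vals = rng.normal(5, 1, size=(60, 12))
    return FeatureMatrix(vals, [f"f{i}" for i in range(60)], [f"s{j}" for j in range(12)])


def score_vector(values, name="custom"):
    values = np.asarray(values, dtype=float)
    return ScoreVector(values, [f"f{i}" for i in range(values.size)], score_name=name)
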