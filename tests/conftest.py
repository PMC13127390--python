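import numpy as np
import pytest
from hypothesis import settings

from rateragree import HER2_SCHEMA, ScoreMatrix

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_matrix(scores, schema=HER2_SCHEMA, case_meta=None, observer_meta=None):
    """Build a ScoreMatrix from a list-of-lists of codes with generated ids."""
    scores = np.asarray(scores, dtype=int)
    n, r = scores.shape
    return ScoreMatrix(
        case_ids=[f"c{i}" for i in range(n)],
        observer_ids=[f"o{j}" for j in range(r)],
        scores=scores,
        schema=schema,
        case_meta=case_meta,
        observer_meta=observer_meta,
    )


def random_matrix(rng, n, r, n_categories=4):
    return make_matrix(rng.integers(0, n_categories, size=(n, r)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def toy_matrix():
    """6 cases x 4 observers with a mix of unanimous and split cases."""
    return make_matrix(
        [
            [0, 0, 0, 0],  # unanimous 0
            [0, 1, 0, 1],  # 0/1+ split
            [2, 2, 2, 2],  # unanimous 2+
            [1, 2, 2, 2],
            [3, 3, 3, 2],
            [3, 3, 3, 3],  # unanimous 3+
        ]
    )
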