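import numpy as np
import pytest

from pmssa.delphi import RatingMatrix
from pmssa.hierarchy import load_hierarchy


@pytest.fixture(scope="session")
def hierarchy():
    """The packaged published weighting table (5 domains, 18
    characteristics, 84 items)."""
    return load_hierarchy()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_rating_matrix(arr, **kw) -> RatingMatrix:
    arr = np.asarray(arr)
    m, n = arr.shape
    return RatingMatrix(
        ratings=arr,
        item_ids=kw.pop("item_ids", tuple(f"i{j}" for j in range(n))),
        expert_ids=kw.pop("expert_ids", tuple(f"e{i}" for i in range(m))),
        **kw,
    )
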