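import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from icutriage import RatingMatrix, SimulationConfig

settings.register_profile("default", derandomize=True, database=None, deadline=None)
settings.load_profile("default")


@pytest.fixture
def small_matrix() -> RatingMatrix:
    """Three raters on five vignettes, no missing cells, with a reference."""
    ratings = pd.DataFrame(
        {
            "r1": [1, 2, 3, 4, 2],
            "r2": [1, 2, 4, 4, 2],
            "r3": [2, 2, 3, 3, 1],
        },
        index=pd.Index([1, 2, 3, 4, 5], name="vignette_id"),
    )
    reference = pd.Series([1, 2, 3, 4, 2], index=ratings.index)
    return RatingMatrix(ratings, reference=reference, category_count=4)


@pytest.fixture
def tiny_config() -> SimulationConfig:
    """A down-scaled study configuration for fast end-to-end runs."""
    return SimulationConfig(
        seed=11,
        n_vignettes=12,
        n_raters=4,
        reference_distribution=(3, 3, 3, 3),
        cohort_n=80,
        cohort_priority_counts=(20, 20, 20, 15),
        n_bootstrap=50,
    )
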