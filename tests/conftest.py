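import numpy as np
import pytest

from chronotyper.core_data import AbundanceMatrix
from chronotyper.synthetic import month_grid_dates


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, month_indices=None, ids=None):
    """Small AbundanceMatrix on the study calendar grid."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, T = values.shape
    months = list(range(T)) if month_indices is None else list(month_indices)
    dates = month_grid_dates(max(months) + 1)
    return AbundanceMatrix(
        ids or [f"v{i}" for i in range(n)],
        [dates[m] for m in months],
        np.array(months) - months[0],
        values,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
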