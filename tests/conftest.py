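import numpy as np
import pandas as pd
import pytest

from gscaboot import ModelSpec, build_population


@pytest.fixture(scope="session")
def pop_model():
    return build_population()


@pytest.fixture
def one_block_spec():
    return ModelSpec(blocks={"c1": ["a", "b"]}, paths=[])


@pytest.fixture
def two_block_spec():
    return ModelSpec(
        blocks={"c1": ["a", "b", "c"], "c2": ["d", "e", "f"]},
        paths=[("c1", "c2")],
    )


def exact_correlation_pair(r: float, reps: int = 3) -> pd.DataFrame:
    """Two columns whose divisor-n sample correlation is exactly ``r``.

    Built from two orthogonal mean-zero patterns with sum of squares n.
    """
    u1 = np.tile([1.0, 1.0, -1.0, -1.0], reps)
    u2 = np.tile([1.0, -1.0, 1.0, -1.0], reps)
    z2 = r * u1 + np.sqrt(1.0 - r**2) * u2
    return pd.DataFrame({"a": u1, "b": z2})


@pytest.fixture
def corr_pair():
    return exact_correlation_pair
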