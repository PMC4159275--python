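import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fixture_matrix() -> pd.DataFrame:
    """8 localities x 10 taxa binary matrix (fixed; used for frozen oracles)."""
    X = np.array(
        [
            [0, 1, 0, 0, 1, 0, 0, 0, 1, 0],
            [1, 0, 0, 0, 1, 1, 0, 1, 0, 0],
            [0, 1, 0, 0, 0, 1, 0, 1, 1, 0],
            [0, 0, 1, 1, 0, 1, 1, 0, 1, 0],
            [1, 0, 0, 1, 0, 0, 1, 1, 0, 1],
            [1, 1, 0, 0, 0, 0, 0, 0, 1, 1],
            [0, 0, 0, 0, 0, 0, 0, 1, 1, 1],
            [1, 1, 0, 1, 1, 1, 1, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return pd.DataFrame(
        X,
        index=[f"L{i}" for i in range(8)],
        columns=[f"sp{j}" for j in range(10)],
    )


@pytest.fixture
def small_pool():
    from paleobeta.synthetic import generate_species_pool

    return generate_species_pool(40, seed=11)


@pytest.fixture
def small_drivers():
    from paleobeta.synthetic import generate_driver_series

    return generate_driver_series(5, phi=0.3, innovation_sd=30.0, trend=450.0, seed=11)


@pytest.fixture
def small_record(small_pool, small_drivers):
    from paleobeta.synthetic import TaphonomyParams, generate_fossil_record

    taph = TaphonomyParams(n_localities=40)
    return generate_fossil_record(small_pool, small_drivers, taph, seed=11)
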