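import numpy as np
import pytest

from tailsplit import (
    build_count_tables,
    generate_rating_fixture,
    impute_missing_counts,
)


@pytest.fixture(scope="session")
def asym_tables():
    """Imputed count tables from the default asymmetric-reliability fixture."""
    matrix = generate_rating_fixture(seed=20)
    return impute_missing_counts(build_count_tables(matrix))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
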