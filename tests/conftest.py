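import numpy as np
import pandas as pd
import pytest

from chronodiet import GeneratorConfig, generate_cohort
from chronodiet.fmt_ffq import ProductReference


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n=400, seed=123))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_products():
    return {
        "p1": ProductReference("p1", "product one", 30.0, 3.5),
        "p2": ProductReference("p2", "product two", 100.0, 1.0),
        "p3": ProductReference("p3", "per-serving product", 50.0, 40.0,
                               units="ng_per_serving"),
    }
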