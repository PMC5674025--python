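import pytest
from hypothesis import HealthCheck, settings

import herbnet as hn

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic study shared across read-only tests."""
    return hn.gen_full_study(seed=11)


@pytest.fixture
def tiny_records():
    return [
        hn.IngredientRecord("H01", "H01_C001", "a", 45.0, 0.30),
        hn.IngredientRecord("H01", "H01_C002", "b", 30.0, 0.18),
        hn.IngredientRecord("H02", "H02_C001", "c", 29.9, 0.50),
        hn.IngredientRecord("ML", "ML_C001", "d", 80.0, 0.05, exempt=True),
    ]
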