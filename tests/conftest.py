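import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def physchem_config():
    from operomics.physchem import default_config

    return default_config()


@pytest.fixture()
def random_sequences():
    """100 reproducible random protein sequences of varied length."""
    rng = random.Random(20240901)
    return [
        "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(10, 300)))
        for _ in range(100)
    ]
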