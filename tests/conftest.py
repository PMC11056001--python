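import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

MITO_ANCHOR = "TACGACCTCGATGTTGGATCA"
BARCODE_ANCHOR = "CGAAATCGGTAGACGCTACG"


@pytest.fixture
def rng():
    return random.Random(20230913)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(n))
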