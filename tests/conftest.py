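import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import mappability as mp


@pytest.fixture(scope="session")
def small_repeat_genome():
    """2 kb genome, one 5-copy family (divergence 1), one N gap."""
    ref, truth = mp.generate_genome(
        2000, [mp.RepeatSpec(40, 5, 1)], gap_spec=mp.GapSpec(1, 25), seed=3
    )
    return ref, truth


@pytest.fixture(scope="session")
def random_dna():
    rng = np.random.default_rng(7)

    def make(length: int, seed=None) -> str:
        r = rng if seed is None else np.random.default_rng(seed)
        return "".join(r.choice(list("ACGT"), length))

    return make
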