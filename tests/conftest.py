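import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: worked "rescue" example: rejected by the strict preset (the single
#: AT step is rated 0 and splits it into two 7-bp fragments), accepted
#: whole by the permissive preset.
MIXED_EXAMPLE = "GCGTGCATGTGTGC"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet),
                                                         size=length)])


@pytest.fixture
def planted_fasta(tmp_path):
    """A small planted-motif fixture pair (FASTA + truth BED)."""
    from zdnascan.synthetic_fixtures import write_fixture

    return write_fixture(tmp_path, seed=11, n_sequences=2, length=400)
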