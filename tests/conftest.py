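import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tfconcord.motifs import pfm_to_pwm
from tfconcord.pipeline import run_synthetic_screen

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ac_pwm():
    """Two-position motif with near-certain A then C (counts 8, pc 0.25)."""
    counts = [[8, 0, 0, 0], [0, 8, 0, 0]]
    return pfm_to_pwm(counts, pseudocount=0.25, tf_id="AC")


@pytest.fixture(scope="session")
def flat_pwm():
    """Motif whose probabilities equal the background everywhere."""
    import numpy as np
    from tfconcord.motifs import PWM

    return PWM(tf_id="FLAT", probs=np.full((4, 4), 0.25))


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted-repressor study shared across tests."""
    return run_synthetic_screen(
        seed=11, n_genes=300, n_decoys=5, promoter_length=200,
        motif_length=8, planted_fraction=0.3, effect_size=1.5,
    )


def random_pwm(rng, length):
    counts = rng.integers(0, 30, size=(length, 4))
    return pfm_to_pwm(counts, pseudocount=0.5, tf_id="RND")


def random_sequence(rng, length):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
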