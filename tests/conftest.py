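import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spice.motif_io import BackgroundModel, consensus_to_pwm

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def uniform_bg():
    return BackgroundModel.uniform()


@pytest.fixture
def ap1_pwm():
    """AP1-like primary motif used across the suite."""
    return consensus_to_pwm("TGACTCA", id="AP1", match_prob=0.85)


@pytest.fixture
def irf_pwm():
    """IRF-half-site-like secondary motif."""
    return consensus_to_pwm("TGAAAC", id="IRF", match_prob=0.85)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_window(rng, width=500, window_id="w0", gc=0.5):
    """A background-only window drawn from a Markov-0 model."""
    from spice._seq import decode
    from spice.peaks_windows import SequenceWindow

    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return SequenceWindow(
        window_id=window_id, chrom="chrT", win_start=0,
        seq=decode(rng.choice(4, size=width, p=p)),
    )
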