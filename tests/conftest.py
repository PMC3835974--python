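import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from synplast import CDParams, PairStdpParams, SpikeTrain

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def pair_vc23():
    """Window time constants of the visual-cortex L2/3 dataset, balanced rule."""
    return PairStdpParams(tau_pre=0.014, tau_post=0.042, q=1.0, c_w=1.0)


@pytest.fixture
def cd_generic():
    """A CD parameter set with every mechanism active (no fixture values)."""
    return CDParams(tau_pre=0.014, tau_post=0.042, tau_rec_pre=0.3,
                    tau_rec_post=0.1, c_pre=0.5, c_post=0.4, q_min=0.5,
                    tau_q=0.1, c_q=2.0, theta_q=0.05, c_w=0.02)


def random_trains(rng, n_pre=(1, 5), n_post=(1, 5), t_max=0.15):
    """Random (pre, post) trains with distinct times, for property batteries."""
    npre = rng.integers(*n_pre, endpoint=True)
    npost = rng.integers(*n_post, endpoint=True)
    times = rng.uniform(0, t_max, size=npre + npost)
    while len(np.unique(times)) != times.size:
        times = rng.uniform(0, t_max, size=npre + npost)
    return (SpikeTrain(np.sort(times[:npre]), "pre"),
            SpikeTrain(np.sort(times[npre:]), "post"))
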