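import numpy as np
import pytest

from measleep.io import SpikeTrainSet


@pytest.fixture
def rng():
    return np.random.default_rng(20160707)


@pytest.fixture
def small_spikes():
    """Two-channel toy spike set over [0, 10) s."""
    return SpikeTrainSet(
        trains={
            "e1": np.array([0.2, 0.5, 1.0, 1.05, 1.10, 1.15, 5.0]),
            "e2": np.array([0.9, 1.02, 1.08, 1.14, 7.5]),
        },
        t_start_s=0.0,
        t_end_s=10.0,
    )


def random_train(rng, n_max=30, span=(0.0, 10.0), min_gap=1e-3):
    """Sorted strictly-increasing random train with up to n_max spikes."""
    n = int(rng.integers(1, n_max + 1))
    ts = np.sort(rng.uniform(span[0], span[1], size=n))
    keep = np.r_[True, np.diff(ts) > min_gap]
    return ts[keep]
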