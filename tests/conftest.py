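import numpy as np
import pytest

from burstnet import BurstParams


def brute_force_bursts(times_s, min_spikes=20, max_isi_ms=20.0):
    """Independent maximal-run scanner: pure-Python, one pass, no numpy
    splitting. Returns (t_start, t_end, n_spikes) tuples."""
    out = []
    run = []
    eps = 1e-12
    for t in times_s:
        if run and (t - run[-1]) > max_isi_ms / 1000.0 + eps:
            if len(run) >= min_spikes:
                out.append((run[0], run[-1], len(run)))
            run = []
        run.append(t)
    if len(run) >= min_spikes:
        out.append((run[0], run[-1], len(run)))
    return out


def random_spike_train(rng, max_spikes=200):
    """Random train mixing short (burst-like) and long ISIs, in seconds."""
    n = rng.integers(0, max_spikes + 1)
    if n == 0:
        return np.empty(0)
    kind = rng.random(n)
    isis = np.where(
        kind < 0.7,
        rng.uniform(0.0005, 0.025, n),  # straddles the 20 ms boundary
        rng.uniform(0.025, 2.0, n),
    )
    # sprinkle exact-boundary ISIs to exercise the inclusive cutoff
    exact = rng.random(n) < 0.05
    isis[exact] = 0.020
    return np.cumsum(isis)


@pytest.fixture
def burst_params():
    return BurstParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
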