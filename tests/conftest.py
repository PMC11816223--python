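import numpy as np
import pytest

from fivedct.phantom import WaveformSpec, make_default_phantom, simulate_session
from fivedct.surrogate import BreathingTrace, SurrogateSignal, compute_rate

SMALL_GRID = (32, 32, 24)
SMALL_VOXEL = (8.0, 8.0, 5.0)


@pytest.fixture(scope="session")
def phantom():
    return make_default_phantom(SMALL_GRID, SMALL_VOXEL)


@pytest.fixture(scope="session")
def small_session(phantom):
    """An 8-scan noisy session used by most integration tests."""
    return simulate_session(phantom, WaveformSpec(seed=1), n_scans=8)


@pytest.fixture(scope="session")
def static_phantom():
    p = make_default_phantom(SMALL_GRID, SMALL_VOXEL)
    p.alpha_true = np.zeros_like(p.alpha_true)
    p.beta_true = np.zeros_like(p.beta_true)
    return p


@pytest.fixture()
def sinusoid_signal():
    """A clean 4 s-period breathing signal with known analytic derivative."""
    t = np.arange(0, 60, 0.01)
    A = np.sin(2 * np.pi * t / 4.0)
    sig = SurrogateSignal(t=t, A=A)
    return compute_rate(sig)


def make_trace(t, v):
    return BreathingTrace(t=np.asarray(t, float), v_raw=np.asarray(v, float))
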