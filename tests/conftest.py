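import numpy as np
import pytest

from sleepphys import synthio as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cycle_matrix():
    """Deterministic W -> N -> R -> W cycle."""
    return np.array([[0.0, 1.0, 0.0],
                     [0.0, 0.0, 1.0],
                     [1.0, 0.0, 0.0]])


@pytest.fixture
def sleepy_matrix():
    """Plausible bout-level sleep structure (zero diagonal)."""
    return np.array([[0.0, 0.95, 0.05],
                     [0.60, 0.0, 0.40],
                     [0.80, 0.20, 0.0]])


@pytest.fixture
def resonant_params():
    """Linear membrane whose analytic impedance peaks near 4 Hz."""
    return syn.MembraneParams(g_l=5.0, c=150.0, g_1=10.36, tau_w=150.0)


@pytest.fixture
def passive_params():
    """Pure RC membrane (no slow branch)."""
    return syn.MembraneParams(g_l=5.0, c=150.0, g_1=0.0)
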