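import numpy as np
import pytest

from mssecnn import preprocess, synthgen


@pytest.fixture(scope="session")
def small_coupled_recording():
    """120 s, 4-channel recording with one unidirectional Alpha2 edge (0 -> 1)."""
    cfg = synthgen.SimConfig(
        n_channels=4,
        duration=120.0,
        coupling_edges=[synthgen.CouplingEdge(0, 1, "Alpha2", 10, 0.6)],
        class_effect=0.0,
    )
    return synthgen.simulate_recording(cfg, "pre", seed=0)


@pytest.fixture(scope="session")
def coupled_segments(small_coupled_recording):
    return preprocess.preprocess_recording(small_coupled_recording)


@pytest.fixture(scope="session")
def default_recording():
    """One 16-channel recording with the default coupling layout."""
    cfg = synthgen.SimConfig(duration=20.0)
    return synthgen.simulate_recording(cfg, "pre", seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
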