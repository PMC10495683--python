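import numpy as np
import pytest

from simplemux import PhantomSpec, default_stain_matrix, generate_control_points, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def stain_matrix():
    return default_stain_matrix()


@pytest.fixture(scope="session")
def small_phantom():
    """A compact default-panel phantom with jittered control points attached."""
    spec = PhantomSpec(seed=11, height=128, width=128)
    acquisitions, truth = generate_phantom(spec)
    for i, acq in enumerate(acquisitions[1:], start=1):
        acq.control_points = generate_control_points(
            truth, acq.antigen, n_points=12, jitter_sigma_px=0.5, seed=100 + i)
    return spec, acquisitions, truth
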