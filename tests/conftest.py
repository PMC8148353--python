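import numpy as np
import pytest

from trace_concord import TraceMask
from trace_concord.synthetic_tracing import ObserverModel, default_config


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def circle_trace():
    """Factory for rasterized filled circles built from the implicit
    equation (independent of the package's rasterizers)."""

    def make(shape=(201, 201), center=(100.0, 100.0), radius=50.0):
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        return TraceMask((xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2)

    return make


@pytest.fixture
def small_study_config():
    """A fast 6-image study (small images, elliptic truths)."""
    return default_config(
        seed=42,
        counts={"glaucoma": 2, "dr": 2, "normal": 2},
        dataset_shapes={"drishti": (240, 360), "aria": (220, 300)},
        perturbation_amplitude={"glaucoma": 0.0, "dr": 0.0, "normal": 0.0},
    )


@pytest.fixture
def noiseless_observer():
    return ObserverModel(
        radial_jitter_sd=0.0, misalignment_prob=0.0, smoothing_window=1
    )
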