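import numpy as np
import pytest

from beatkit.io import HeartAnnotation
from beatkit.synthetic import (
    HeartSimConfig,
    simulate_brightfield_movie,
    synthetic_annotation,
)


@pytest.fixture(scope="session")
def bright_config():
    return HeartSimConfig(seed=3)


@pytest.fixture(scope="session")
def bright_movie(bright_config):
    """One default brightfield movie with its ground truth and annotation."""
    movie, truth = simulate_brightfield_movie(bright_config)
    annotation = synthetic_annotation(bright_config)
    return movie, truth, annotation


@pytest.fixture
def parallel_annotation():
    """Two straight parallel walls 10 px apart, AV marker mid-way."""
    x = np.linspace(0.0, 100.0, 21)
    return HeartAnnotation(
        wall_a=np.column_stack([x, np.zeros_like(x)]),
        wall_b=np.column_stack([x, np.full_like(x, 10.0)]),
        av_marker_a=10,
        av_marker_b=10,
        pixel_width=1.92,
    )
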