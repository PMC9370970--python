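import numpy as np
import pytest

import tubershape as ts


@pytest.fixture(scope="session")
def regular_sample():
    """A rendered unperturbed-ellipse capture with its ground truth."""
    spec = ts.ShapeSpec(a=120, b=80, theta=0.5, lobe_count=0,
                        boundary_jitter=0.5, seed=3)
    return ts.render_sample(spec)


@pytest.fixture(scope="session")
def irregular_sample():
    """A rendered 6-lobe capture, amplitude 0.25 of the local radius."""
    spec = ts.ShapeSpec(a=120, b=80, theta=0.5, lobe_count=6, lobe_amplitude=0.25,
                        lobe_phase=1.0, boundary_jitter=1.0, seed=4)
    return ts.render_sample(spec)


@pytest.fixture(scope="session")
def regular_mask(regular_sample):
    return ts.preprocess_pipeline(regular_sample.image)


@pytest.fixture(scope="session")
def irregular_mask(irregular_sample):
    return ts.preprocess_pipeline(irregular_sample.image)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def disc_mask(shape=(101, 101), center=None, radius=30.0):
    h, w = shape
    cy, cx = center if center else ((h - 1) / 2, (w - 1) / 2)
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
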