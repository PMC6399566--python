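"""Shared fixtures: one rendered phantom reused across the suite.

Phantom rendering at full frame size costs about a second, so the
standard 20-degree sample (and its ROI crop and detected boxes) is
built once per session.
"""

import warnings

import numpy as np
import pytest

from spinecurve.detect import detect_vertebrae
from spinecurve.phantom import generate_phantom, scoliotic_spec
from spinecurve.roi import isolate_spine_roi


@pytest.fixture(scope="session")
def phantom20():
    """A 20-degree right-convex phantom with full ground truth."""
    return generate_phantom(scoliotic_spec(20.0, seed=3))


@pytest.fixture(scope="session")
def straight_phantom():
    from spinecurve.phantom import PhantomSpec

    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def roi20(phantom20):
    return isolate_spine_roi(phantom20.image)


@pytest.fixture(scope="session")
def boxes20(roi20):
    _, crop = roi20
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return detect_vertebrae(crop)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
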