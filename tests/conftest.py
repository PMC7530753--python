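"""Shared fixtures: built tube models are expensive, so they are session
scoped and each test takes a fresh copy of the particle state via
``model.reset()`` rather than rebuilding."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from perisim.builder import build_tube, get_preset

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_model():
    return build_tube(get_preset("tiny"))


@pytest.fixture(scope="session")
def desk3d_model():
    return build_tube(get_preset("desk3d"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
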