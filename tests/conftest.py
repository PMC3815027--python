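"""Shared fixtures and deterministic hypothesis configuration."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_population():
    """Six rendered nuclei with the default channels (shared, read-only)."""
    from spermfish3d import generate_population

    return generate_population(6, 0.5, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_object(voxels, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0),
                label=1, channel="test"):
    """Helper: build a SegmentedObject from a list of (z, y, x) indices."""
    from spermfish3d.segmentation import SegmentedObject

    return SegmentedObject(
        label=label,
        channel=channel,
        voxels=np.asarray(voxels, dtype=int),
        shape=tuple(shape),
        spacing=tuple(spacing),
    )
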