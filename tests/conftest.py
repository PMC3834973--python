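"""Shared fixtures: phantoms, geometry, and cached simulations.

Simulations are expensive (forward projection + FBP), so everything a
test might share is session-scoped and memoized.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrmar import (
    Geometry,
    PhysicsConfig,
    default_head_spec,
    default_implants,
    fbp_reconstruct,
    forward_project,
    insert_implants,
    make_phantom,
    simulate_artifact_ct,
)


@pytest.fixture(scope="session")
def head_spec():
    return default_head_spec(128)


@pytest.fixture(scope="session")
def clean_phantom(head_spec):
    return make_phantom(head_spec)


@pytest.fixture(scope="session")
def geom(clean_phantom):
    return Geometry.default_for(clean_phantom.shape, clean_phantom.pixel_spacing)


@pytest.fixture(scope="session")
def clean_reference(clean_phantom, geom):
    """FBP of the clean phantom's sinogram — the scoring ground truth."""
    return fbp_reconstruct(forward_project(clean_phantom, geom), clean_phantom.shape)


@pytest.fixture(scope="session")
def simulate_condition(clean_phantom, geom):
    """Memoized (implant_count, seed) -> (artifact, metal_mask, ct_with_metal)."""
    cache: dict[tuple[int, int], tuple] = {}

    def _run(count: int, seed: int):
        key = (count, seed)
        if key not in cache:
            ct_metal, metal_mask = insert_implants(clean_phantom, default_implants(count))
            artifact, _ = simulate_artifact_ct(
                ct_metal, metal_mask, geom, PhysicsConfig(), seed
            )
            cache[key] = (artifact, metal_mask, ct_metal)
        return cache[key]

    return _run


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
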