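"""Shared fixtures: small deterministic phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from tesvox.phantoms import PhantomSpec, make_layered_sphere, make_slab


@pytest.fixture(scope="session")
def sphere_2mm():
    """Standard 4-layer head sphere at 2 mm (read-only; copy before mutating)."""
    spec = PhantomSpec(kind="layered_sphere", voxel_mm=2.0, margin_voxels=4)
    return make_layered_sphere(spec)


@pytest.fixture(scope="session")
def small_sphere():
    """A small, cheap 3-layer sphere for electrode/pipeline tests."""
    spec = PhantomSpec(
        kind="layered_sphere",
        radii_mm=(20.0, 24.0, 30.0),
        tissues=("gm", "skull", "scalp"),
        voxel_mm=2.0,
        margin_voxels=4,
    )
    return make_layered_sphere(spec)


@pytest.fixture(scope="session")
def cube_slab():
    """Homogeneous 50 mm cube at 2 mm with z-margin for plate electrodes."""
    spec = PhantomSpec(
        kind="slab",
        thicknesses_mm=(50.0,),
        tissues=("gm",),
        voxel_mm=2.0,
        margin_voxels=3,
    )
    return make_slab(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
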