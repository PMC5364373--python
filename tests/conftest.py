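"""Shared fixtures: small synthetic cohorts and canonical geometry.

Everything is generated at run time from fixed seeds; session scope keeps
the expensive artifacts (cohort masks, templates, fits) shared across
test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from hippomorph.masks import VoxelMask
from hippomorph.synth import ShapeParams, canonical_mesh, make_cohort
from hippomorph.template_fit import build_template


@pytest.fixture(scope="session")
def default_params() -> ShapeParams:
    return ShapeParams()


@pytest.fixture(scope="session")
def canonical(default_params):
    return canonical_mesh(default_params)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort with the default planted effect (seed 1)."""
    return make_cohort(6, seed=1)


@pytest.fixture(scope="session")
def left_masks(small_cohort):
    return [s["left"] for s in small_cohort.masks]


@pytest.fixture(scope="session")
def left_template(left_masks):
    return build_template(left_masks)


def make_sphere_mask(radius_mm: float, shape=(32, 32, 32),
                     voxel=(1.0, 1.0, 1.3)) -> VoxelMask:
    """Digitized sphere centered on the grid (anisotropic voxels)."""
    aff = np.diag([*voxel, 1.0])
    center = (np.asarray(shape) - 1) / 2.0
    aff[:3, 3] = -center * np.asarray(voxel)
    idx = np.indices(shape).reshape(3, -1).T
    world = idx @ aff[:3, :3].T + aff[:3, 3]
    inside = (world ** 2).sum(axis=1) <= radius_mm ** 2
    return VoxelMask(inside.reshape(shape), aff)
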