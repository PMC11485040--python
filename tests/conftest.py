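"""Shared fixtures: a desk-scale phantom, tracking config, and blueprint
inputs reused across the unit-test modules (session-scoped, built once)."""

import dataclasses

import numpy as np
import pytest

from tractspace.blueprints import build_tract_matrix
from tractspace.imaging import BinaryMask, VolumeGrid, downsample_mask
from tractspace.phantom import (
    FiberOrientationField,
    PhantomSpec,
    make_phantom_brain,
    make_twin_pair,
)
from tractspace.tracking import (
    TrackingConfig,
    run_protocol_tractography,
    run_surface_seeded_tractography,
)
from tractspace.tract_metrics import normalise


@pytest.fixture(scope="session")
def phantom():
    return make_phantom_brain(PhantomSpec(seed=7, n_vertices=250))


@pytest.fixture(scope="session")
def fast_cfg():
    return TrackingConfig(streamlines_per_seed_voxel=15,
                          streamlines_per_surface_vertex=80, seed=5)


@pytest.fixture(scope="session")
def coarse_mask(phantom):
    return downsample_mask(phantom.brain_mask, 2.0)


@pytest.fixture(scope="session")
def phantom_npds(phantom, fast_cfg):
    return [
        normalise(run_protocol_tractography(
            phantom.field, p.rois, phantom.brain_mask, fast_cfg),
            tract=p.name)
        for p in phantom.protocols.protocols
    ]


@pytest.fixture(scope="session")
def tract_matrix(phantom_npds, coarse_mask):
    return build_tract_matrix(phantom_npds, coarse_mask)


@pytest.fixture(scope="session")
def surface_conn(phantom, coarse_mask, fast_cfg):
    return run_surface_seeded_tractography(
        phantom.field, phantom.surface, phantom.brain_mask, coarse_mask,
        fast_cfg)


@pytest.fixture(scope="session")
def small_twin():
    return make_twin_pair(PhantomSpec(seed=3, n_vertices=250, noise=0.0),
                          seed=11)


def make_uniform_field(shape=(20, 20, 20), direction=(1.0, 0.0, 0.0),
                       fraction=0.9, voxel=1.0):
    """Single-orientation field filling a cube, with a centered affine."""
    shape = tuple(shape)
    affine = np.eye(4) * voxel
    affine[3, 3] = 1.0
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    dirs = np.zeros(shape + (3, 3))
    dirs[..., 0, :] = d
    fracs = np.zeros(shape + (3,))
    fracs[..., 0] = fraction
    field = FiberOrientationField(dirs, fracs, affine)
    mask = BinaryMask(np.ones(shape, dtype=bool), affine)
    return field, mask


@pytest.fixture()
def uniform_field():
    return make_uniform_field()


def grid_of(values, voxel=1.0):
    affine = np.eye(4)
    affine[:3, :3] *= voxel
    return VolumeGrid(np.asarray(values, dtype=float), affine)


def mask_of(values, voxel=1.0):
    affine = np.eye(4)
    affine[:3, :3] *= voxel
    return BinaryMask(np.asarray(values, dtype=bool), affine)
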