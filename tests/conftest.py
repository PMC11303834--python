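"""Shared fixtures: phantoms are generated once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

import myomap
from myomap.orientation import OrientationConfig


@pytest.fixture(scope="session")
def lv_small():
    """Small annular LV phantom (64^3), noise-free, twisted helix law."""
    spec = myomap.LVPhantomSpec(
        shape=(64, 64, 64), inner_radius_um=280.0, outer_radius_um=520.0, seed=1
    )
    volume, labelmap, truth = myomap.generate_lv_phantom(spec)
    return spec, volume, labelmap, truth


@pytest.fixture(scope="session")
def lv_full():
    """Full-size LV phantom (128^3, 20 µm voxels) at SNR 10, fixed seed."""
    spec = myomap.LVPhantomSpec(snr=10.0, seed=11)
    volume, labelmap, truth = myomap.generate_lv_phantom(spec)
    return spec, volume, labelmap, truth


@pytest.fixture(scope="session")
def lv_full_orientation(lv_full):
    """Structure-tensor orientation of the full-size phantom (wall-masked)."""
    spec, volume, labelmap, truth = lv_full
    tensors = myomap.compute_structure_tensor(
        volume, OrientationConfig(mask=truth.wall_mask)
    )
    field = myomap.extract_fiber_orientation(
        tensors, OrientationConfig(mask=truth.wall_mask)
    )
    return tensors, field


@pytest.fixture(scope="session")
def flat_slab():
    """Flat 200/2000/400 µm three-layer slab at 20 µm voxels, axis-aligned."""
    spec = myomap.WallSlabSpec(shape=(160, 48, 48))
    volume, labelmap = myomap.generate_wall_slab(spec)
    return spec, volume, labelmap


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
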