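"""Shared fixtures: small intrinsics and phantoms sized for unit tests."""

import numpy as np
import pytest

import coloct


@pytest.fixture(scope="session")
def air_intrinsics():
    """Full-fidelity source, uniform-k sweep, for closed-form PSF work."""
    return coloct.ProbeIntrinsics(sweep_mode="linear_k")


@pytest.fixture(scope="session")
def small_phantom():
    """Small normal-wall phantom (coarse voxels) for geometry tests."""
    return coloct.make_normal_wall_phantom(
        extent_mm=(2.0, 1.5, 2.2), layer_thicknesses=(0.3, 0.1, 1.6),
        vessel_count=2, voxel_size=0.02, seed=3)


@pytest.fixture(scope="session")
def scan_intr():
    return coloct.scan_intrinsics()


def make_speckle_sector(rng, shape=(64, 32), pitch_um=4.0):
    """Synthetic fully developed speckle B-scan (exponential intensity)."""
    inten = rng.exponential(1.0, size=shape)
    angles = np.linspace(-10, 10, shape[1])
    return coloct.BScanSector(np.sqrt(inten), angles, pitch_um)
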