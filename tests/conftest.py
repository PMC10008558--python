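import numpy as np
import pytest

from trackmel.psf_pattern import (
    BeamGeometry,
    PSFStack,
    build_synthetic_psf,
    build_tracking_pattern,
    shot_displacements,
)


@pytest.fixture(scope="session")
def geometry():
    return BeamGeometry()


@pytest.fixture(scope="session")
def schedule(geometry):
    return build_tracking_pattern(geometry=geometry)


@pytest.fixture(scope="session")
def psf(geometry):
    """Full-resolution (10 nm) synthetic three-Gaussian excitation PSF."""
    return build_synthetic_psf(geometry)


@pytest.fixture(scope="session")
def displacements_all(schedule, geometry):
    return shot_displacements(schedule, geometry)


@pytest.fixture(scope="session")
def flat_psf():
    """Spatially uniform unit-intensity stack, for closed-form likelihoods."""
    return PSFStack(
        np.ones((5, 5, 5), dtype=float), (100.0, 100.0, 100.0), (-200.0, -200.0, -200.0)
    )


def gaussian_stack(waist_xyz=(300.0, 300.0, 600.0), voxel=(10.0, 10.0, 10.0),
                   half_extent=(600.0, 600.0, 900.0), center=(0.0, 0.0, 0.0)):
    """Analytic single-Gaussian stack used as an interpolation oracle."""
    axes = [
        -h + v * np.arange(int(2 * h / v) + 1) for h, v in zip(half_extent, voxel)
    ]
    zz, yy, xx = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
    vals = np.exp(
        -2.0 * (xx - center[0]) ** 2 / waist_xyz[0] ** 2
        - 2.0 * (yy - center[1]) ** 2 / waist_xyz[1] ** 2
        - 2.0 * (zz - center[2]) ** 2 / waist_xyz[2] ** 2
    )
    return PSFStack(vals, voxel, (axes[0][0], axes[1][0], axes[2][0]))
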