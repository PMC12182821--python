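import numpy as np
import pytest

from sweepflow.phantom import PhantomConfig, VesselSpec, build_phantom


@pytest.fixture(scope="session")
def small_tube_phantom():
    """Steady 100 cm/s tube, radius 4 mm, 1 mm voxels (4 voxels/radius)."""
    cfg = PhantomConfig(
        grid_shape=(24, 24, 16),
        voxel_size_mm=1.0,
        rr_jitter_frac=0.0,
        vessels=(
            VesselSpec(
                name="tube",
                centerline=[[0.0, 0.0, -20.0], [0.0, 0.0, 20.0]],
                radius_mm=4.0,
                peak_velocity_cm_s=100.0,
            ),
        ),
    )
    return build_phantom(cfg, 4)


@pytest.fixture(scope="session")
def bifurcation_phantom():
    """Parent tube splitting 60/40 into two children, steady flow."""
    cfg = PhantomConfig(
        grid_shape=(48, 48, 32),
        voxel_size_mm=1.0,
        rr_jitter_frac=0.0,
        vessels=(
            VesselSpec(
                name="parent",
                centerline=[[0.0, 0.0, -40.0], [0.0, 0.0, 0.0]],
                radius_mm=5.0,
                peak_velocity_cm_s=80.0,
            ),
            VesselSpec(
                name="left",
                centerline=[[0.0, 0.0, 0.0], [8.0, 0.0, 6.0], [8.0, 0.0, 40.0]],
                radius_mm=4.0,
                peak_velocity_cm_s=0.0,
                branch_of=("parent", 0.6),
            ),
            VesselSpec(
                name="right",
                centerline=[[0.0, 0.0, 0.0], [-8.0, 0.0, 6.0], [-8.0, 0.0, 40.0]],
                radius_mm=4.0,
                peak_velocity_cm_s=0.0,
                branch_of=("parent", 0.4),
            ),
        ),
    )
    return build_phantom(cfg, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
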