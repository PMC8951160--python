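import numpy as np
import pytest

import ctcloud as cc


@pytest.fixture(scope="session")
def small_spec() -> cc.PhantomSpec:
    """A fast phantom with one crack and two pores for unit tests."""
    return cc.default_spec(
        grid=(96, 64, 48),
        spacing=cc.VoxelSpacing(50.0, 50.0, 50.0),
        axes=(2100.0, 1300.0, 1000.0),
        cracks=(cc.Crack(normal=(0.0, 1.0, 0.0), offset=150.0, width=160.0, depth_fraction=0.7),),
        n_pores=2,
        pore_radius=(200.0, 280.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return cc.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def segmented_config(small_spec) -> cc.ReconstructionConfig:
    return cc.ReconstructionConfig(
        mode="segmented",
        spacing=small_spec.spacing,
        feature_window=cc.GreyWindow(110, 130),
    )


def voxelize_points(points: np.ndarray, spacing: cc.VoxelSpacing, shape) -> np.ndarray:
    """Map physical point coordinates back onto a (nz, ny, nx) boolean grid."""
    out = np.zeros(shape, dtype=bool)
    if len(points) == 0:
        return out
    k = np.round(points[:, 2] / spacing.dz - 1).astype(int)
    i = np.round(points[:, 1] / spacing.dy).astype(int)
    j = np.round(points[:, 0] / spacing.dx).astype(int)
    out[k, i, j] = True
    return out


def mask_points(mask: np.ndarray, spacing: cc.VoxelSpacing) -> np.ndarray:
    """Physical coordinates of every True voxel of a (nz, ny, nx) mask."""
    idx = np.argwhere(mask)
    return np.column_stack(
        (idx[:, 2] * spacing.dx, idx[:, 1] * spacing.dy, (idx[:, 0] + 1) * spacing.dz)
    )
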