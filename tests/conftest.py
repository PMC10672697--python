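"""Shared fixtures: analytic phantoms and small synthetic structures."""

import numpy as np
import pytest

from boneadapt import EmbeddingField, Volume3D, grf_structure

SPACING = 61.0


def sphere_sdf(n: int, radius_vox: float, spacing: float = SPACING) -> EmbeddingField:
    """Exact signed distance field of a sphere centered in an n^3 grid."""
    ax = np.arange(n) - (n - 1) / 2.0
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    return EmbeddingField(phi=(r - radius_vox) * spacing, spacing=spacing)


def sphere_binary(n: int, radius_vox: float, spacing: float = SPACING) -> Volume3D:
    ax = np.arange(n) - (n - 1) / 2.0
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    return Volume3D(data=(r <= radius_vox).astype(np.uint8), spacing=spacing)


def plane_sdf(n: int, offset_vox: float = None, spacing: float = SPACING) -> EmbeddingField:
    """Exact SDF of a plane normal to axis 0 (zero level between centers)."""
    if offset_vox is None:
        offset_vox = (n - 1) / 2.0 + 0.5
    phi = (np.arange(n) - offset_vox)[:, None, None] * np.ones((n, n, n))
    return EmbeddingField(phi=phi * spacing, spacing=spacing)


def measured_radius(vol: Volume3D) -> float:
    """Sphere radius (um) back-computed from the bone voxel count."""
    return (3.0 * vol.bone_voxels() / (4.0 * np.pi)) ** (1.0 / 3.0) * vol.spacing


@pytest.fixture(scope="session")
def grf_small() -> Volume3D:
    return grf_structure((32, 32, 32), SPACING, target_bvtv=25.0,
                         correlation_length=260.0, seed=42)


@pytest.fixture(scope="session")
def grf_medium() -> Volume3D:
    return grf_structure((48, 48, 48), SPACING, target_bvtv=25.0,
                         correlation_length=260.0, seed=7)
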