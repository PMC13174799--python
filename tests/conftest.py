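import numpy as np
import pytest

from mitomorph.grids import LabelVolume


def digitized_sphere_labels(radius_vox: int, spacing: float = 1.0) -> LabelVolume:
    """Binary sphere of the given voxel radius, labeled as object 1."""
    n = 2 * radius_vox + 7
    c = n / 2.0  # sphere centered between voxels, like the rasterizer
    z, y, x = np.mgrid[:n, :n, :n]
    mask = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_vox**2
    return LabelVolume(mask.astype(np.int32), (spacing,) * 3)


@pytest.fixture(scope="session")
def sphere_r12():
    return digitized_sphere_labels(12)


@pytest.fixture(scope="session")
def sphere_r10():
    return digitized_sphere_labels(10)


@pytest.fixture(scope="session")
def seeded_field():
    """10 disjoint primitives with analytic truth (session-cached)."""
    from mitomorph.phantoms import random_field

    return random_field(10, seed=42)


@pytest.fixture(scope="session")
def seeded_field_metrics(seeded_field):
    from mitomorph.morph3d import measure_objects

    return measure_objects(seeded_field.labels)


def disc_mask(radius_px: int, pad: int = 3) -> np.ndarray:
    n = 2 * radius_px + 2 * pad
    c = n / 2.0
    y, x = np.mgrid[:n, :n]
    return (y + 0.5 - c) ** 2 + (x + 0.5 - c) ** 2 <= radius_px**2
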