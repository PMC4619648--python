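import numpy as np
import pytest
import trimesh

from braincast import BinaryMask, PhantomSpec, generate_phantom


def digitized_sphere(shape, center, radius_vox, spacing=1.0):
    idx = np.indices(shape, dtype=float)
    r2 = sum((idx[d] - center[d]) ** 2 for d in range(3))
    return BinaryMask(grid=(r2 <= radius_vox**2).astype(np.uint8), spacing=(spacing,) * 3)


@pytest.fixture(scope="session")
def sphere_mask_r20():
    """Digitized sphere of radius 20 voxels, unit spacing, off-lattice centre."""
    return digitized_sphere((50, 50, 50), (24.5, 24.5, 24.5), 20.0)


@pytest.fixture(scope="session")
def bumpy_blob():
    """Asymmetric closed mesh with no rotational symmetry (registration target)."""
    base = trimesh.creation.icosphere(3, radius=3.0)
    v = base.vertices.copy()
    v[:, 0] *= 1.6
    v[:, 2] *= 0.7
    v += 0.25 * np.sin(2.1 * v[:, [1, 2, 0]])
    return trimesh.Trimesh(vertices=v, faces=base.faces, process=False)


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom pair (seed 1), shared across tests."""
    return generate_phantom(PhantomSpec(seed=1))
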