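import numpy as np
import pytest

from occuscale import Blob, PhantomSpec, VolumeGrid, build_spherical_kernel, make_phantom
from occuscale.phantoms import interior_mask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def kernel5():
    return build_spherical_kernel(5)


@pytest.fixture
def two_blob_spec():
    """Noise-free phantom: one full-scale and one half-scale soft sphere."""
    return PhantomSpec(
        shape=(64, 64, 64),
        blobs=(
            Blob(center=(20.0, 20.0, 20.0), radius=14.0, true_scale=1.0),
            Blob(center=(44.0, 44.0, 44.0), radius=14.0, true_scale=0.5),
        ),
    )


@pytest.fixture
def two_blob_phantom(two_blob_spec):
    f, true_scale, f_ideal = make_phantom(two_blob_spec)
    full = interior_mask(two_blob_spec, two_blob_spec.blobs[0])
    half = interior_mask(two_blob_spec, two_blob_spec.blobs[1])
    return {
        "spec": two_blob_spec,
        "f": f,
        "true_scale": true_scale,
        "f_ideal": f_ideal,
        "full_region": full,
        "half_region": half,
    }


@pytest.fixture
def noise_volume(rng):
    """Pure N(0, 0.1^2) noise volume."""
    return VolumeGrid(rng.normal(0.0, 0.1, size=(48, 48, 48)).astype(np.float32))


def textured_region_blobs(center, blur_sigma):
    """A plateau body carrying fine bumps: blur lowers the texture peaks
    while the interior plateau survives, emulating B-factor loss on
    atomic detail."""
    cz, cy, cx = center
    blobs = [Blob(center=center, radius=14.0, amplitude=0.6, true_scale=1.0,
                  blur_sigma=blur_sigma)]
    for dz in (-5, 0, 5):
        for dy in (-5, 0, 5):
            for dx in (-5, 0, 5):
                blobs.append(
                    Blob(center=(cz + dz, cy + dy, cx + dx), radius=1.8,
                         amplitude=0.4, true_scale=1.0, blur_sigma=blur_sigma)
                )
    return blobs
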