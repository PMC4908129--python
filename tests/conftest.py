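import nibabel as nib
import numpy as np
import pytest

from voxelwise.volio import mask_from_array


def write_nifti(path, data, affine=None):
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    """Full 4x4x4 mask (tau = 64)."""
    return mask_from_array(np.ones((4, 4, 4)))


@pytest.fixture
def nifti_writer(tmp_path):
    def _write(name, data, affine=None):
        return write_nifti(tmp_path / name, data, affine)

    return _write
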