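import math

import nibabel as nib
import numpy as np
import pytest

from reactfc.synth import SynthConfig, simulate_cohort


def make_img(data, voxel_mm=2.0, tr=None):
    """Wrap an array as a NIfTI image on a simple axis-aligned grid."""
    data = np.asarray(data, dtype=float)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = -np.asarray(data.shape[:3]) / 2.0 * voxel_mm
    img = nib.Nifti1Image(data, affine)
    if data.ndim == 4 and tr is not None:
        zooms = list(img.header.get_zooms()[:3]) + [float(tr)]
        img.header.set_zooms(zooms)
    return img


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noise-free cohort: the generative model is exactly invertible."""
    cfg = SynthConfig(n_subjects=3, snr=math.inf, pet_noise_frac=0.0, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions (n=16, SNR 1)."""
    return simulate_cohort(SynthConfig(seed=21))
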