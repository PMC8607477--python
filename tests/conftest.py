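import numpy as np
import pytest

from mrinorm.grid import Cohort, CohortImage, ROISet, VolumeGrid
from mrinorm.synthetic import PhantomSpec, generate_cohort, preset


@pytest.fixture(scope="session")
def het_cohort():
    """One heterogeneous-acquisition phantom cohort (15 patients)."""
    return generate_cohort(preset("het_like", seed=1), label="het")


@pytest.fixture(scope="session")
def hom_cohort():
    """One homogeneous-acquisition phantom cohort (15 patients)."""
    return generate_cohort(preset("hom_like", seed=1), label="hom")


@pytest.fixture(scope="session")
def degenerate_spec():
    """Spec with no heterogeneity and no noise: all patients identical."""
    return PhantomSpec(
        n_patients=4,
        gain_range=(1.0, 1.0),
        offset_range=(0.0, 0.0),
        bias_amplitude=0.0,
        noise_sd=0.0,
        seed=7,
    )


def pure_gain_cohort(gains, seed=3, offset=0.0):
    """Noiseless cohort whose patients differ only by a multiplicative gain.

    Gains that are powers of two keep all per-patient images bit-exact
    affine copies of the base phantom.
    """
    spec = PhantomSpec(
        n_patients=len(gains),
        gain_range=(1.0, 1.0),
        offset_range=(0.0, 0.0),
        bias_amplitude=0.0,
        noise_sd=0.0,
        seed=seed,
    )
    base = generate_cohort(spec, label="base")
    patients = []
    for gain, patient in zip(gains, base):
        vol = patient.volume.with_voxels(gain * patient.volume.voxels + offset)
        patients.append(
            CohortImage(
                volume=vol, rois=patient.rois, external_mask=patient.external_mask
            )
        )
    return Cohort(label="pure_gain", patients=patients)


def two_patient_cohort(vox_a, vox_b, roi="CSF_inf"):
    """Tiny two-patient cohort with a single evaluated ROI covering all voxels."""
    patients = []
    for pid, vox in (("A", vox_a), ("B", vox_b)):
        arr = np.asarray(vox, dtype=float).reshape(-1, 1, 1)
        vol = VolumeGrid(patient_id=pid, voxels=arr, spacing=(1, 1, 1))
        mask = np.ones(arr.shape, dtype=bool)
        patients.append(
            CohortImage(
                volume=vol, rois=ROISet(grid_ref=pid, masks={roi: mask})
            )
        )
    return Cohort(label="tiny", patients=patients)
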