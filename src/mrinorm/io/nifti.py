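"""NIfTI-1 volume and label-map I/O.

The internal axis order (row, column, slice) maps straight onto the NIfTI
data array; the affine columns carry the row, column and slice direction
cosines scaled by the voxel pitch, all in patient-space mm. Label maps are
integer volumes with a JSON sidecar giving the label -> ROI-name table.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np

from ..grid import ROISet, VolumeGrid

__all__ = ["read_nifti", "write_nifti", "write_labelmap", "read_labelmap"]


def _affine(volume: VolumeGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = volume.index_to_patient_matrix
    aff[:3, 3] = volume.origin
    return aff


def write_nifti(volume: VolumeGrid, path: os.PathLike) -> Path:
    """Write a volume as .nii/.nii.gz with float32 intensities."""
    path = Path(path)
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), _affine(volume))
    nib.save(img, path)
    return path


def read_nifti(path: os.PathLike, patient_id: str | None = None) -> VolumeGrid:
    """Read a NIfTI volume written by :func:`write_nifti` (or compatible)."""
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    aff = img.affine
    m = aff[:3, :3]
    dy, dx, dz = (float(np.linalg.norm(m[:, j])) for j in range(3))
    orientation = m / np.array([dy, dx, dz])
    if patient_id is None:
        patient_id = path.name.removesuffix(".gz").removesuffix(".nii")
    return VolumeGrid(
        patient_id=patient_id,
        voxels=data,
        spacing=(dx, dy, dz),
        origin=tuple(float(v) for v in aff[:3, 3]),
        orientation=orientation,
    )


def write_labelmap(
    rois: ROISet, grid: VolumeGrid, path: os.PathLike
) -> tuple[Path, Path]:
    """Write ROI masks as an integer label volume plus a JSON name table.

    Labels are assigned 1..n in sorted ROI-name order; overlapping masks are
    resolved in favour of the later label (masks from the phantom generator
    are disjoint by construction).
    """
    path = Path(path)
    labels = np.zeros(grid.shape, dtype=np.int16)
    table: dict[str, str] = {}
    for label, name in enumerate(sorted(rois.names()), start=1):
        labels[rois[name]] = label
        table[str(label)] = name
    img = nib.Nifti1Image(labels, _affine(grid))
    nib.save(img, path)
    sidecar = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
    sidecar.write_text(json.dumps(table, indent=2))
    return path, sidecar


def read_labelmap(
    path: os.PathLike, grid: VolumeGrid, sidecar: os.PathLike | None = None
) -> ROISet:
    """Read an integer label volume + JSON sidecar back into an ROISet."""
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_name(
            path.name.removesuffix(".gz").removesuffix(".nii") + ".json"
        )
    table = json.loads(Path(sidecar).read_text())
    labels = np.asarray(nib.load(path).dataobj).astype(int)
    masks = {name: labels == int(label) for label, name in table.items()}
    return ROISet(grid_ref=grid.patient_id, masks=masks, shape=grid.shape)
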