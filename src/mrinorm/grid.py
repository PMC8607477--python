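"""In-memory image model: volumes, ROI mask sets, cohort containers.

Conventions (fixed package-wide):

* voxel arrays are indexed ``[row, column, slice]``, 0-based;
* all physical coordinates are patient-space millimetres (DICOM LPS);
* ``spacing`` is ``(dx, dy, dz)`` — column pitch, row pitch, slice pitch;
* ``orientation`` is a 3x3 matrix whose columns are the unit direction
  cosines of increasing row, column and slice index respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

from .errors import MrinormError
from .vocab import ALLOWED_ROIS

__all__ = ["VolumeGrid", "ROISet", "CohortImage", "Cohort"]


def _default_orientation() -> np.ndarray:
    # axial, identity cosines: row -> +y, column -> +x, slice -> +z
    m = np.zeros((3, 3))
    m[1, 0] = 1.0  # row direction
    m[0, 1] = 1.0  # column direction
    m[2, 2] = 1.0  # slice direction
    return m


@dataclass
class VolumeGrid:
    """One patient's 3-D scalar image with its geometry.

    Parameters
    ----------
    patient_id : str
        Unique patient identifier within a cohort.
    voxels : ndarray, shape (rows, columns, slices)
        Scalar intensities in arbitrary (scanner-dependent) units.
    spacing : (dx, dy, dz)
        Voxel pitch in mm along column, row and slice index.
    origin : (x, y, z)
        Patient-space position of voxel (0, 0, 0), mm.
    orientation : (3, 3) ndarray
        Direction-cosine columns for the row, column and slice axes.
    series_meta : dict
        Optional acquisition tags carried through from the source series.
    """

    patient_id: str
    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=_default_orientation)
    series_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.shape[2] < 1:
            raise MrinormError(
                f"voxels must be 3-D with >= 1 slice, got shape {self.voxels.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MrinormError(f"spacing components must be > 0, got {self.spacing}")
        self.origin = tuple(float(v) for v in self.origin)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3):
            raise MrinormError("orientation must be a 3x3 direction-cosine matrix")
        if not np.all(np.isfinite(self.voxels)):
            raise MrinormError("voxel array contains non-finite values")

    # -- geometry helpers --------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def index_to_patient_matrix(self) -> np.ndarray:
        """3x3 matrix M with patient = origin + M @ (row, col, slice)."""
        dx, dy, dz = self.spacing
        return self.orientation @ np.diag([dy, dx, dz])

    def index_to_patient(self, index: np.ndarray) -> np.ndarray:
        """Map fractional (row, col, slice) indices to patient-space mm."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        return (self.index_to_patient_matrix @ idx.T).T + np.asarray(self.origin)

    def patient_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map patient-space mm points to fractional (row, col, slice) indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.origin)
        inv = np.linalg.inv(self.index_to_patient_matrix)
        return (inv @ pts.T).T

    def with_voxels(self, voxels: np.ndarray) -> "VolumeGrid":
        """Copy of this grid carrying new intensities on identical geometry."""
        return replace(self, voxels=np.asarray(voxels, dtype=float))


@dataclass
class ROISet:
    """Named binary masks congruent with one :class:`VolumeGrid`."""

    grid_ref: str
    masks: dict[str, np.ndarray]
    shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, mask in self.masks.items():
            if name not in ALLOWED_ROIS:
                raise MrinormError(
                    f"ROI name {name!r} is not in the controlled vocabulary"
                )
            arr = np.asarray(mask, dtype=bool)
            if arr.ndim != 3:
                raise MrinormError(f"mask {name!r} must be 3-D")
            clean[name] = arr
        shapes = {m.shape for m in clean.values()}
        if self.shape is None and shapes:
            self.shape = next(iter(shapes))
        if self.shape is not None and shapes - {self.shape}:
            raise MrinormError("ROI masks differ in shape from the referenced grid")
        self.masks = clean

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self) -> list[str]:
        return list(self.masks)


@dataclass
class CohortImage:
    """A patient's volume bundled with its ROI masks and optional body mask."""

    volume: VolumeGrid
    rois: ROISet
    external_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rois.grid_ref != self.volume.patient_id:
            raise MrinormError(
                f"ROISet references grid {self.rois.grid_ref!r} but volume is "
                f"{self.volume.patient_id!r}"
            )
        if self.rois.shape is not None and self.rois.shape != self.volume.shape:
            raise MrinormError("ROI masks are not congruent with the volume")
        if self.external_mask is not None:
            self.external_mask = np.asarray(self.external_mask, dtype=bool)
            if self.external_mask.shape != self.volume.shape:
                raise MrinormError("external mask is not congruent with the volume")

    @property
    def patient_id(self) -> str:
        return self.volume.patient_id


@dataclass
class Cohort:
    """An ordered set of patients analysed together."""

    label: str
    patients: list[CohortImage]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise MrinormError(f"duplicate patient ids in cohort {self.label!r}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[CohortImage]:
        return iter(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def volumes(self) -> Mapping[str, VolumeGrid]:
        return {p.patient_id: p.volume for p in self.patients}
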