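"""DICOM-RT Structure Set rasterization and export.

Contour polygons live in patient-space mm on (approximately) axial planes.
Rasterization converts each closed planar contour to grid index space,
assigns it to the nearest slice within a tolerance, and fills it with the
voxel-center containment rule:

    a voxel belongs to the polygon iff its center is inside, with a
    half-open boundary convention — a center exactly on an edge counts as
    inside only on the minimal-coordinate side.

The rule is implemented with an even–odd crossing test that is independent
of contour vertex orientation (clockwise vs counter-clockwise).
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.sequence import Sequence
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from shapely.geometry import box
from shapely.ops import unary_union

from ..errors import MissingSliceError, MrinormError, UnknownROIError
from ..grid import ROISet, VolumeGrid
from ..vocab import ALLOWED_ROIS

__all__ = ["rasterize_polygon", "rasterize_structures", "write_rtstruct"]

_RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"


def rasterize_polygon(
    vertices: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Fill a closed polygon given in continuous (row, col) index coordinates.

    Voxel centers sit at integer indices. Returns a boolean (rows, cols)
    mask under the half-open voxel-center containment rule.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise MrinormError("polygon needs >= 3 (row, col) vertices")
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    if len(verts) < 3:
        raise MrinormError("degenerate polygon")

    rows, cols = shape
    r0 = max(int(np.floor(verts[:, 0].min())), 0)
    r1 = min(int(np.ceil(verts[:, 0].max())), rows - 1)
    c0 = max(int(np.floor(verts[:, 1].min())), 0)
    c1 = min(int(np.ceil(verts[:, 1].max())), cols - 1)
    mask = np.zeros(shape, dtype=bool)
    if r1 < r0 or c1 < c0:
        return mask

    rc = np.arange(r0, r1 + 1)
    cc = np.arange(c0, c1 + 1)
    R, C = np.meshgrid(rc, cc, indexing="ij")
    inside = np.zeros(R.shape, dtype=bool)

    # even-odd crossing test along the column axis; the half-open comparison
    # (r1 <= R) != (r2 <= R) plus the strict C < c_intersect makes boundary
    # centers belong only on the minimal-coordinate side, independent of
    # vertex ordering.
    v1 = verts
    v2 = np.roll(verts, -1, axis=0)
    for (ra, ca), (rb, cb) in zip(v1, v2):
        if ra == rb:
            continue  # edge parallel to the scan axis never crosses
        crosses = (ra <= R) != (rb <= R)
        with np.errstate(invalid="ignore"):
            c_int = ca + (R - ra) * (cb - ca) / (rb - ra)
        inside ^= crosses & (C < c_int)

    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return mask


def _structure_names(rtstruct: pydicom.Dataset) -> dict[int, str]:
    return {
        int(item.ROINumber): str(item.ROIName)
        for item in rtstruct.StructureSetROISequence
    }


def rasterize_structures(
    rtstruct: os.PathLike | pydicom.Dataset,
    grid: VolumeGrid,
    name_map: dict[str, str] | None = None,
    *,
    on_unknown: str = "warn",
    slice_tolerance: float | None = None,
) -> ROISet:
    """Rasterize a DICOM-RT Structure Set onto ``grid``.

    Parameters
    ----------
    rtstruct : path or pydicom Dataset
        The structure-set file.
    grid : VolumeGrid
        Target geometry; contours must share its frame of reference.
    name_map : dict, optional
        Mapping from raw structure names to the controlled ROI vocabulary.
        Names already in the vocabulary pass through unchanged.
    on_unknown : {"warn", "raise", "skip"}
        Policy for structures whose names cannot be canonicalized.
    slice_tolerance : float, optional
        Maximum |contour z - slice z| in mm; default half the slice spacing.

    Raises
    ------
    MissingSliceError
        If a contour plane matches no slice within tolerance.
    UnknownROIError
        If ``on_unknown == "raise"`` and a name is not mappable.
    """
    if not isinstance(rtstruct, pydicom.Dataset):
        rtstruct = pydicom.dcmread(rtstruct)
    name_map = dict(name_map or {})
    if slice_tolerance is None:
        slice_tolerance = grid.spacing[2] / 2.0

    grid_frame = grid.series_meta.get("FrameOfReferenceUID")
    try:
        rt_frame = str(
            rtstruct.ReferencedFrameOfReferenceSequence[0].FrameOfReferenceUID
        )
    except (AttributeError, IndexError):
        rt_frame = None
    if grid_frame and rt_frame and grid_frame != rt_frame:
        raise MrinormError(
            "structure set frame of reference does not match the image series"
        )

    names = _structure_names(rtstruct)
    masks: dict[str, np.ndarray] = {}
    for roi_contour in rtstruct.ROIContourSequence:
        number = int(roi_contour.ReferencedROINumber)
        raw = names.get(number, f"ROI_{number}")
        canonical = name_map.get(raw, raw)
        if canonical not in ALLOWED_ROIS:
            msg = f"structure {raw!r} is not mappable to the ROI vocabulary"
            if on_unknown == "raise":
                raise UnknownROIError(msg)
            if on_unknown == "warn":
                warnings.warn(msg, stacklevel=2)
            continue

        mask = masks.setdefault(canonical, np.zeros(grid.shape, dtype=bool))
        for contour in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            idx = grid.patient_to_index(pts)
            k_float = float(idx[:, 2].mean())
            k = int(round(k_float))
            if k < 0 or k >= grid.shape[2] or (
                abs(k_float - k) * grid.spacing[2] > slice_tolerance + 1e-9
            ):
                raise MissingSliceError(
                    f"contour of {canonical!r} at slice index {k_float:.3f} "
                    f"matches no slice within {slice_tolerance} mm"
                )
            mask[:, :, k] |= rasterize_polygon(idx[:, :2], grid.shape[:2])

    return ROISet(grid_ref=grid.patient_id, masks=masks, shape=grid.shape)


# ---------------------------------------------------------------------------
# Export: masks -> contour polygons
# ---------------------------------------------------------------------------

def _mask_slice_polygons(mask2d: np.ndarray) -> list[np.ndarray]:
    """Outline a 2-D mask as the exact boundary of its voxel squares.

    Each voxel is a unit square centered on its integer index; the union's
    exterior rings are returned as (row, col) vertex arrays. Mask centers are
    strictly inside these rings, so rasterizing them back is lossless.
    """
    rr, cc = np.nonzero(mask2d)
    if rr.size == 0:
        return []
    squares = [box(c - 0.5, r - 0.5, c + 0.5, r + 0.5) for r, c in zip(rr, cc)]
    merged = unary_union(squares)
    geoms = getattr(merged, "geoms", [merged])
    polys = []
    for geom in geoms:
        xy = np.asarray(geom.exterior.coords)  # (col, row) order from shapely
        polys.append(np.column_stack([xy[:, 1], xy[:, 0]]))
    return polys


def write_rtstruct(
    rois: ROISet,
    grid: VolumeGrid,
    path: os.PathLike,
) -> Path:
    """Write ``rois`` as a DICOM-RT Structure Set referencing ``grid``."""
    path = Path(path)
    frame_uid = grid.series_meta.get("FrameOfReferenceUID", generate_uid())

    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = _RTSTRUCT_STORAGE
    sop_uid = generate_uid()
    ds.file_meta.MediaStorageSOPInstanceUID = sop_uid
    ds.SOPClassUID = _RTSTRUCT_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.PatientID = grid.patient_id
    ds.PatientName = grid.patient_id
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.StructureSetLabel = "mrinorm"

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = frame_uid
    ds.ReferencedFrameOfReferenceSequence = Sequence([ref_frame])

    struct_seq, contour_seq = [], []
    for number, name in enumerate(sorted(rois.names()), start=1):
        item = Dataset()
        item.ROINumber = number
        item.ROIName = name
        item.ReferencedFrameOfReferenceUID = frame_uid
        item.ROIGenerationAlgorithm = "AUTOMATIC"
        struct_seq.append(item)

        rc = Dataset()
        rc.ReferencedROINumber = number
        contours = []
        mask = rois[name]
        for k in range(mask.shape[2]):
            for poly in _mask_slice_polygons(mask[:, :, k]):
                idx = np.column_stack([poly[:, 0], poly[:, 1], np.full(len(poly), k)])
                pts = grid.index_to_patient(idx)
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(pts)
                c.ContourData = [float(v) for v in pts.ravel()]
                contours.append(c)
        rc.ContourSequence = Sequence(contours)
        contour_seq.append(rc)

    ds.StructureSetROISequence = Sequence(struct_seq)
    ds.ROIContourSequence = Sequence(contour_seq)
    ds.save_as(path, enforce_file_format=True)
    return path
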