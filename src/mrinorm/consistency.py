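"""Cohort-level ROI intensity-consistency metric (NMI_c and SD NMI_c).

For a single type of healthy tissue, a good standardization should make
intensities similar within and across patients. The metric scores this per
contoured ROI:

* NMI_c(i, r) — patient i's mean intensity inside ROI r, divided by the
  cohort-level intensity range of that ROI (extrema of the pooled voxel
  intensities of ROI r across all patients). The division makes the value
  dimensionless and invariant to a global rescaling of the cohort.
* SD NMI_c(r) — the sample standard deviation (n - 1 denominator) of
  NMI_c(·, r) across the cohort's patients. An ideal standardization drives
  it toward 0; larger values mean the ROI's tissue intensity is less
  consistent across patients.

The cheek-fat ROIs are excluded from evaluation because they serve as the
reference tissue of the Fat standardization method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyMaskError,
    InsufficientCohortError,
    ZeroRangeError,
)
from .grid import Cohort, VolumeGrid
from .standardize import StandardizationMethod, run_method
from .vocab import EVALUATED_ROIS, METHOD_NAMES

__all__ = [
    "roi_mean",
    "NMITable",
    "SDNMIcTable",
    "compute_nmi_table",
    "compute_sd_nmi_c",
    "evaluate_cohort",
]


def roi_mean(volume: VolumeGrid | np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of the voxel intensities under a non-empty mask."""
    arr = volume.voxels if isinstance(volume, VolumeGrid) else np.asarray(volume)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("ROI mask selects no voxels")
    return float(arr[mask].mean())


@dataclass
class NMITable:
    """Per-(patient, ROI) normalized mean intensities for one method."""

    cohort_label: str
    method: str
    entries: pd.DataFrame           # index: patient_id, columns: roi
    cohort_ranges: pd.DataFrame     # index: roi, columns: ["min", "max"]


@dataclass
class SDNMIcTable:
    """Per-(method, ROI) consistency statistics for one cohort."""

    cohort_label: str
    values: pd.DataFrame            # index: method, columns: roi
    method_summary: pd.DataFrame    # index: method, columns: ["mean", "sd"]

    def to_tidy(self) -> pd.DataFrame:
        """Long form: cohort, method, roi, value."""
        long = self.values.reset_index(names="method").melt(
            id_vars="method", var_name="roi", value_name="value"
        )
        long.insert(0, "cohort", self.cohort_label)
        return long


def compute_nmi_table(
    cohort: Cohort,
    method_output: Mapping[str, VolumeGrid],
    evaluated_rois: Sequence[str] = EVALUATED_ROIS,
    *,
    method: str = "",
    pooled_range: bool = False,
) -> NMITable:
    """Normalized mean intensities of every (patient, ROI) pair.

    ``method_output`` maps patient_id -> standardized volume. The cohort
    range of ROI r is (min, max) of the pooled voxel intensities of r across
    all patients; with ``pooled_range=True`` a single range pooled over all
    evaluated ROIs is used instead (alternative reading, off by default).
    """
    if len(cohort) < 2:
        raise InsufficientCohortError("NMI_c needs a cohort of >= 2 patients")

    pooled: dict[str, list[np.ndarray]] = {r: [] for r in evaluated_rois}
    means: dict[str, dict[str, float]] = {r: {} for r in evaluated_rois}
    for patient in cohort:
        vol = method_output[patient.patient_id]
        for roi in evaluated_rois:
            mask = patient.rois[roi]
            if not mask.any():
                raise EmptyMaskError(
                    f"ROI {roi!r} of patient {patient.patient_id!r} is empty"
                )
            vals = vol.voxels[mask]
            pooled[roi].append(vals)
            means[roi][patient.patient_id] = float(vals.mean())

    if pooled_range:
        allvals = np.concatenate([v for r in evaluated_rois for v in pooled[r]])
        lo, hi = float(allvals.min()), float(allvals.max())
        ranges = {r: (lo, hi) for r in evaluated_rois}
    else:
        ranges = {}
        for roi in evaluated_rois:
            vals = np.concatenate(pooled[roi])
            ranges[roi] = (float(vals.min()), float(vals.max()))

    entries = pd.DataFrame(index=cohort.patient_ids, columns=list(evaluated_rois),
                           dtype=float)
    for roi in evaluated_rois:
        lo, hi = ranges[roi]
        if hi <= lo:
            raise ZeroRangeError(f"pooled intensity range of ROI {roi!r} is zero")
        for pid, mu in means[roi].items():
            entries.loc[pid, roi] = mu / (hi - lo)

    range_df = pd.DataFrame(ranges, index=["min", "max"]).T
    return NMITable(
        cohort_label=cohort.label,
        method=method,
        entries=entries,
        cohort_ranges=range_df,
    )


def compute_sd_nmi_c(table: NMITable) -> pd.Series:
    """Sample SD (n - 1) of NMI_c over patients, per ROI."""
    if len(table.entries) < 2:
        raise InsufficientCohortError("SD NMI_c needs >= 2 patients per ROI")
    return table.entries.std(axis=0, ddof=1)


def evaluate_cohort(
    cohort: Cohort,
    methods: Sequence[str | StandardizationMethod] = METHOD_NAMES,
    evaluated_rois: Sequence[str] = EVALUATED_ROIS,
    *,
    pooled_range: bool = False,
) -> SDNMIcTable:
    """Run each standardization method and score SD NMI_c per evaluated ROI.

    Returns a table with one row per method, one column per evaluated ROI,
    plus a per-method mean +/- SD summary across ROIs.
    """
    rows = {}
    for method in methods:
        name = method if isinstance(method, str) else method.name
        output = run_method(cohort, method)
        nmi = compute_nmi_table(
            cohort, output, evaluated_rois, method=name, pooled_range=pooled_range
        )
        rows[name] = compute_sd_nmi_c(nmi)

    values = pd.DataFrame(rows).T
    values = values[list(evaluated_rois)]
    summary = pd.DataFrame(
        {"mean": values.mean(axis=1), "sd": values.std(axis=1, ddof=1)}
    )
    return SDNMIcTable(
        cohort_label=cohort.label, values=values, method_summary=summary
    )
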