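"""Intensity standardization transformers for weighted MRI.

Voxel intensities of conventional T1-/T2-weighted MRI are in arbitrary,
scanner-dependent units, so cohort-level quantitative analysis requires a
per-image standardizing transform f(x). Five methods are provided, each as a
scikit-learn-style transformer (``fit`` learns the per-image or per-cohort
parameters, ``transform`` applies the intensity map to every voxel):

``MinMaxStandardizer``
    f(x) = (x - min x) / (max x - min x), rescaling each image to [0, 1].
``ZScoreStandardizer``
    f(x) = (x - mu) / sigma with mu, sigma taken over the whole image
    (*Z-All*) or over a body "external" mask (*Z-External*). Population
    (divide-by-n) standard deviation.
``FatStandardizer``
    f(x) = x / mu_fat * scale, where mu_fat is the pooled mean over the
    union of the left and right cheek-fat ROIs and scale defaults to 350.
``NyulStandardizer``
    Landmark-percentile histogram standardization: a standard histogram
    template is learned from a cohort (per-landmark mean of each image's
    percentile intensities after mapping [p1, p99] onto a fixed standard
    scale), then each image is mapped onto the template by piecewise-linear
    interpolation between its own landmarks, with linear extrapolation of
    the outermost segments beyond [p1, p99].

All five maps are monotone non-decreasing, so voxel ordering within a
patient is preserved.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import ball
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import (
    DegenerateHistogramError,
    DegenerateVolumeError,
    EmptyMaskError,
    MissingROIError,
    MrinormError,
    NonPositiveReferenceError,
    ZeroRangeError,
    ZeroVarianceError,
)
from .grid import Cohort, ROISet, VolumeGrid
from .vocab import (
    CHEEK_FAT_ROIS,
    FAT_SCALE_DEFAULT,
    NYUL_PERCENTILES_DEFAULT,
    check_method_name,
)

__all__ = [
    "MinMaxStandardizer",
    "ZScoreStandardizer",
    "FatStandardizer",
    "NyulStandardizer",
    "NyulTemplate",
    "MaskConfig",
    "StandardizationMethod",
    "compute_external_mask",
    "standardize_minmax",
    "standardize_zscore",
    "standardize_fat",
    "nyul_learn",
    "nyul_apply",
    "run_method",
]


def _as_array(X) -> np.ndarray:
    if isinstance(X, VolumeGrid):
        return X.voxels
    return np.asarray(X, dtype=float)


def _like(X, voxels: np.ndarray):
    if isinstance(X, VolumeGrid):
        return X.with_voxels(voxels)
    return voxels


# ---------------------------------------------------------------------------
# External (body) mask
# ---------------------------------------------------------------------------

@dataclass
class MaskConfig:
    """Parameters of the body-mask pipeline.

    smoothing_sigma : Gaussian pre-smoothing, in voxels.
    closing_radius : radius of the morphological closing ball, in voxels.
    fill_holes : fill enclosed holes slice-wise after closing.
    """

    smoothing_sigma: float = 1.0
    closing_radius: int = 3
    fill_holes: bool = True


def compute_external_mask(
    volume: VolumeGrid | np.ndarray, cfg: MaskConfig | None = None
) -> np.ndarray:
    """Segment the head-and-neck body region from the background air.

    Pipeline: Gaussian smoothing -> Otsu threshold -> largest connected
    component -> morphological closing -> slice-wise hole fill -> largest
    component again. The result is a single connected foreground component
    with holes filled.

    Raises
    ------
    DegenerateVolumeError
        If the volume is constant (no foreground/background contrast).
    """
    cfg = cfg or MaskConfig()
    arr = _as_array(volume)
    if arr.max() == arr.min():
        raise DegenerateVolumeError("constant volume has no body/background contrast")

    smooth = gaussian(arr, sigma=cfg.smoothing_sigma, preserve_range=True)
    mask = smooth > threshold_otsu(smooth)

    def largest_component(m: np.ndarray) -> np.ndarray:
        labels, n = ndimage.label(m)
        if n == 0:
            raise DegenerateVolumeError("thresholding produced an empty mask")
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        return labels == (1 + int(np.argmax(sizes)))

    mask = largest_component(mask)
    if cfg.closing_radius > 0:
        mask = ndimage.binary_closing(mask, structure=ball(cfg.closing_radius))
    if cfg.fill_holes:
        for k in range(mask.shape[2]):
            mask[:, :, k] = ndimage.binary_fill_holes(mask[:, :, k])
    return largest_component(mask)


# ---------------------------------------------------------------------------
# Per-image affine standardizers
# ---------------------------------------------------------------------------

class MinMaxStandardizer(TransformerMixin, BaseEstimator):
    """Rescale one image's intensity range onto [0, 1].

    Fitted attributes: ``min_``, ``max_``.
    """

    def fit(self, X, y=None):
        arr = _as_array(X)
        self.min_ = float(arr.min())
        self.max_ = float(arr.max())
        if self.max_ <= self.min_:
            raise ZeroRangeError("constant volume: max(x) == min(x)")
        return self

    def transform(self, X):
        check_is_fitted(self, "min_")
        arr = _as_array(X)
        return _like(X, (arr - self.min_) / (self.max_ - self.min_))


class ZScoreStandardizer(TransformerMixin, BaseEstimator):
    """Center at mean 0 / SD 1 over a statistics region.

    With ``mask=None`` the statistics region is the whole image (*Z-All*);
    with a body mask it is the masked voxels (*Z-External*), and the same
    affine map is applied to every voxel of the image. The SD convention is
    population (divide by n).

    Fitted attributes: ``mean_``, ``scale_``.
    """

    def fit(self, X, y=None, mask: np.ndarray | None = None):
        arr = _as_array(X)
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if not mask.any():
                raise EmptyMaskError("statistics mask selects no voxels")
            region = arr[mask]
        else:
            region = arr.ravel()
        self.mean_ = float(region.mean())
        self.scale_ = float(region.std())  # population SD (ddof=0)
        if self.scale_ == 0:
            raise ZeroVarianceError("statistics region has zero variance")
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        arr = _as_array(X)
        return _like(X, (arr - self.mean_) / self.scale_)


class FatStandardizer(TransformerMixin, BaseEstimator):
    """Standardize against the mean cheek-fat intensity.

    f(x) = x / mu_fat * scale, with mu_fat the pooled-voxel mean over the
    union of the Fat_L and Fat_R masks, so a voxel at the cheek-fat mean
    maps exactly to ``scale`` (350 by default).

    Fitted attributes: ``reference_mean_``.
    """

    def __init__(self, scale: float = FAT_SCALE_DEFAULT):
        self.scale = scale

    def fit(self, X, y=None, rois: ROISet | Mapping[str, np.ndarray] | None = None):
        if rois is None:
            raise MissingROIError("Fat standardization requires cheek-fat ROI masks")
        arr = _as_array(X)
        pooled = []
        for name in CHEEK_FAT_ROIS:
            if name not in rois:
                raise MissingROIError(f"required ROI {name!r} is absent")
            mask = np.asarray(rois[name], dtype=bool)
            if not mask.any():
                raise MissingROIError(f"required ROI {name!r} is empty")
            pooled.append(arr[mask])
        self.reference_mean_ = float(np.concatenate(pooled).mean())
        if self.reference_mean_ <= 0:
            raise NonPositiveReferenceError(
                f"cheek-fat mean intensity {self.reference_mean_} is not positive"
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_mean_")
        arr = _as_array(X)
        return _like(X, arr / self.reference_mean_ * self.scale)


# ---------------------------------------------------------------------------
# Nyul landmark histogram standardization
# ---------------------------------------------------------------------------

@dataclass
class NyulTemplate:
    """A learned standard histogram template.

    ``percentiles`` are the landmark percentiles in (0, 100), strictly
    increasing; ``standard_positions`` are the learned standard-scale
    intensities of those landmarks, non-decreasing, with the first and last
    pinned to ``scale_bounds``.
    """

    percentiles: tuple[float, ...]
    standard_positions: tuple[float, ...]
    scale_bounds: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles, dtype=float)
        s = np.asarray(self.standard_positions, dtype=float)
        if p.ndim != 1 or len(p) < 2 or np.any(np.diff(p) <= 0):
            raise MrinormError("percentiles must be strictly increasing")
        if np.any(p <= 0) or np.any(p >= 100):
            raise MrinormError("percentiles must lie in (0, 100)")
        if s.shape != p.shape or np.any(np.diff(s) < 0):
            raise MrinormError("standard_positions must be non-decreasing, same length")
        lo, hi = (float(v) for v in self.scale_bounds)
        if not (np.isclose(s[0], lo) and np.isclose(s[-1], hi)):
            raise MrinormError("template endpoints must equal scale_bounds")
        self.percentiles = tuple(float(v) for v in p)
        self.standard_positions = tuple(float(v) for v in s)
        self.scale_bounds = (lo, hi)

    def to_json(self, path: os.PathLike | None = None) -> str:
        payload = json.dumps(
            {
                "percentiles": list(self.percentiles),
                "standard_positions": list(self.standard_positions),
                "scale_bounds": list(self.scale_bounds),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | os.PathLike) -> "NyulTemplate":
        text = Path(source).read_text() if os.path.exists(str(source)) else str(source)
        d = json.loads(text)
        return cls(
            percentiles=tuple(d["percentiles"]),
            standard_positions=tuple(d["standard_positions"]),
            scale_bounds=tuple(d["scale_bounds"]),
        )


def _landmarks(values: np.ndarray, percentiles: Sequence[float]) -> np.ndarray:
    # linear interpolation between order statistics
    return np.percentile(values, percentiles, method="linear")


def _piecewise_map(
    x: np.ndarray, knots_in: np.ndarray, knots_out: np.ndarray
) -> np.ndarray:
    y = np.interp(x, knots_in, knots_out)
    # linear extrapolation with the outermost segment slopes (no clamping)
    left = x < knots_in[0]
    if left.any():
        slope = (knots_out[1] - knots_out[0]) / (knots_in[1] - knots_in[0])
        y[left] = knots_out[0] + (x[left] - knots_in[0]) * slope
    right = x > knots_in[-1]
    if right.any():
        slope = (knots_out[-1] - knots_out[-2]) / (knots_in[-1] - knots_in[-2])
        y[right] = knots_out[-1] + (x[right] - knots_in[-1]) * slope
    return y


class NyulStandardizer(TransformerMixin, BaseEstimator):
    """Landmark-percentile histogram standardization (cohort-learned).

    ``fit`` learns the standard histogram template from a list of images
    (optionally restricted to each image's body mask); ``transform`` maps a
    new image onto the template piecewise-linearly between its own landmark
    intensities.

    Fitted attributes: ``template_``.
    """

    def __init__(
        self,
        percentiles: Sequence[float] = NYUL_PERCENTILES_DEFAULT,
        scale_bounds: tuple[float, float] = (0.0, 100.0),
        use_mask: bool = True,
    ):
        self.percentiles = percentiles
        self.scale_bounds = scale_bounds
        self.use_mask = use_mask

    def _region(self, X, mask) -> np.ndarray:
        arr = _as_array(X)
        if self.use_mask and mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if not mask.any():
                raise EmptyMaskError("statistics mask selects no voxels")
            return arr[mask]
        return arr.ravel()

    def fit(self, X: Iterable, y=None, masks: Sequence[np.ndarray | None] | None = None):
        images = list(X)
        if not images:
            raise MrinormError("Nyul learning needs at least one image")
        if masks is None:
            masks = [None] * len(images)
        pcts = np.asarray(self.percentiles, dtype=float)
        lo, hi = (float(v) for v in self.scale_bounds)
        mapped = []
        for img, mask in zip(images, masks):
            lm = _landmarks(self._region(img, mask), pcts)
            if lm[-1] <= lm[0]:
                raise DegenerateHistogramError(
                    "p1 and p99 landmarks coincide; histogram is degenerate"
                )
            mapped.append(lo + (lm - lm[0]) * (hi - lo) / (lm[-1] - lm[0]))
        positions = np.mean(mapped, axis=0)
        positions[0], positions[-1] = lo, hi  # exact endpoints
        self.template_ = NyulTemplate(
            percentiles=tuple(pcts),
            standard_positions=tuple(positions),
            scale_bounds=(lo, hi),
        )
        return self

    def transform(self, X, mask: np.ndarray | None = None):
        check_is_fitted(self, "template_")
        arr = _as_array(X)
        lm = _landmarks(self._region(X, mask), np.asarray(self.template_.percentiles))
        if lm[-1] <= lm[0]:
            raise DegenerateHistogramError(
                "p1 and p99 landmarks coincide; histogram is degenerate"
            )
        out = _piecewise_map(
            arr.ravel(), lm, np.asarray(self.template_.standard_positions)
        ).reshape(arr.shape)
        return _like(X, out)


# ---------------------------------------------------------------------------
# Functional wrappers (operation surface)
# ---------------------------------------------------------------------------

def standardize_minmax(volume: VolumeGrid) -> VolumeGrid:
    """Rescale a volume's intensities onto [0, 1]."""
    return MinMaxStandardizer().fit(volume).transform(volume)


def standardize_zscore(
    volume: VolumeGrid, mask: np.ndarray | None = None
) -> VolumeGrid:
    """Z-score a volume; statistics from ``mask`` if given, else all voxels."""
    return ZScoreStandardizer().fit(volume, mask=mask).transform(volume)


def standardize_fat(
    volume: VolumeGrid, rois: ROISet, scale: float = FAT_SCALE_DEFAULT
) -> VolumeGrid:
    """Standardize a volume against its pooled cheek-fat mean intensity."""
    return FatStandardizer(scale=scale).fit(volume, rois=rois).transform(volume)


def _cohort_masks(cohort: Cohort, use_external_mask: bool) -> list[np.ndarray | None]:
    masks: list[np.ndarray | None] = []
    for patient in cohort:
        if not use_external_mask:
            masks.append(None)
        elif patient.external_mask is not None:
            masks.append(patient.external_mask)
        else:
            masks.append(compute_external_mask(patient.volume))
    return masks


def nyul_learn(
    cohort: Cohort,
    percentiles: Sequence[float] = NYUL_PERCENTILES_DEFAULT,
    use_external_mask: bool = True,
    scale_bounds: tuple[float, float] = (0.0, 100.0),
) -> NyulTemplate:
    """Learn a standard histogram template from every patient in a cohort."""
    est = NyulStandardizer(
        percentiles=percentiles, scale_bounds=scale_bounds, use_mask=use_external_mask
    )
    est.fit(
        [p.volume for p in cohort],
        masks=_cohort_masks(cohort, use_external_mask),
    )
    return est.template_


def nyul_apply(
    volume: VolumeGrid,
    template: NyulTemplate,
    mask: np.ndarray | None = None,
) -> VolumeGrid:
    """Map a volume onto a learned template (all voxels transformed)."""
    est = NyulStandardizer(
        percentiles=template.percentiles,
        scale_bounds=template.scale_bounds,
        use_mask=mask is not None,
    )
    est.template_ = template
    return est.transform(volume, mask=mask)


# ---------------------------------------------------------------------------
# Method registry / cohort runner
# ---------------------------------------------------------------------------

@dataclass
class StandardizationMethod:
    """A named method with its parameters, from the fixed vocabulary."""

    name: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_method_name(self.name)


def run_method(
    cohort: Cohort,
    method: str | StandardizationMethod,
) -> dict[str, VolumeGrid]:
    """Apply one standardization method to every patient of a cohort.

    Returns patient_id -> standardized volume. ``Original`` is the identity.
    Errors from individual patients are re-raised tagged with the patient id
    and method name.
    """
    if isinstance(method, str):
        method = StandardizationMethod(method)
    params = method.parameters
    out: dict[str, VolumeGrid] = {}

    if method.name == "Nyul":
        template = params.get("template") or nyul_learn(
            cohort,
            percentiles=params.get("percentiles", NYUL_PERCENTILES_DEFAULT),
            use_external_mask=params.get("use_external_mask", True),
            scale_bounds=params.get("scale_bounds", (0.0, 100.0)),
        )
        for patient in cohort:
            try:
                out[patient.patient_id] = nyul_apply(patient.volume, template)
            except MrinormError as exc:
                raise type(exc)(
                    f"[{method.name}/{patient.patient_id}] {exc}"
                ) from exc
        return out

    for patient in cohort:
        try:
            if method.name == "Original":
                vol = patient.volume
            elif method.name == "MinMax":
                vol = standardize_minmax(patient.volume)
            elif method.name == "Z-All":
                vol = standardize_zscore(patient.volume)
            elif method.name == "Z-External":
                mask = patient.external_mask
                if mask is None:
                    mask = compute_external_mask(patient.volume)
                vol = standardize_zscore(patient.volume, mask=mask)
            elif method.name == "Fat":
                vol = standardize_fat(
                    patient.volume,
                    patient.rois,
                    scale=params.get("scale", FAT_SCALE_DEFAULT),
                )
            else:  # pragma: no cover - guarded by check_method_name
                raise MrinormError(f"unhandled method {method.name!r}")
        except MrinormError as exc:
            raise type(exc)(f"[{method.name}/{patient.patient_id}] {exc}") from exc
        out[patient.patient_id] = vol
    return out
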