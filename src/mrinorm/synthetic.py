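"""Synthetic head-and-neck phantom cohorts with controllable heterogeneity.

Each cohort shares one base phantom: a body ellipsoid of soft tissue inside
an air background, containing 14 small cylindrical ROI shapes (5 slices
each) at T2-weighted-like tissue intensities — CSF and fat bright, muscle
and bone dark. Per-patient acquisition heterogeneity is then emulated by

* a multiplicative gain  g ~ U(gain_range),
* an additive offset     b ~ U(offset_range),
* a smooth multiplicative bias field (second-order polynomial in
  normalized coordinates, peak fractional deviation = bias_amplitude),
* additive Gaussian noise with SD ``noise_sd``.

so patient i sees  g_i * bias_i(r) * base(r) + b_i + noise.  Because the
base phantom (including its within-tissue texture) is drawn once per cohort
and shared, a noiseless bias-free cohort consists of exact per-patient
affine images of one volume — the regime in which the affine-invariant
standardization methods are provably perfect.

Two presets mirror the study design of a multi-scanner cohort versus a
single-protocol cohort: ``het_like`` uses wide gain/offset/bias ranges,
``hom_like`` unit gain, zero offset and small noise only. Both have 15
patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import SpecValidationError, UnknownPresetError
from .grid import Cohort, CohortImage, ROISet, VolumeGrid
from .vocab import HEALTHY_TISSUE_ROIS

__all__ = [
    "RoiShape",
    "PhantomSpec",
    "default_tissue_table",
    "default_roi_layout",
    "preset",
    "generate_cohort",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class RoiShape:
    """A cylindrical ROI: in-plane disc repeated on five adjacent slices."""

    center_row: float
    center_col: float
    z_start: int
    radius: float
    tissue: str
    n_slices: int = 5


def default_tissue_table() -> dict[str, tuple[float, float]]:
    """T2-w-like (mean, within-tissue SD) intensities in arbitrary units."""
    return {
        "csf": (900.0, 45.0),
        "fat": (600.0, 30.0),
        "muscle": (150.0, 8.0),
        "bone": (80.0, 4.0),
        "brain": (350.0, 18.0),
        "background": (20.0, 2.0),
    }


def default_roi_layout() -> dict[str, RoiShape]:
    """Placement of the 14 ROI shapes inside the default 48x48x24 body."""
    r = 2.5
    return {
        "CSF_inf": RoiShape(24, 24, 5, r, "csf"),
        "CSF_mid": RoiShape(24, 24, 10, r, "csf"),
        "CSF_sup": RoiShape(24, 24, 15, r, "csf"),
        "Fat_L": RoiShape(23, 13, 8, r, "fat"),
        "Fat_R": RoiShape(23, 35, 8, r, "fat"),
        "NapeFat_inf": RoiShape(33, 24, 5, r, "fat"),
        "NapeFat_mid": RoiShape(33, 24, 10, r, "fat"),
        "NapeFat_sup": RoiShape(33, 24, 15, r, "fat"),
        "NeckFat": RoiShape(33, 14, 8, r, "fat"),
        "Masseter_L": RoiShape(28, 16, 10, r, "muscle"),
        "Masseter_R": RoiShape(28, 32, 10, r, "muscle"),
        "RCPM": RoiShape(31, 30, 5, r, "muscle"),
        "Skull": RoiShape(15, 24, 13, r, "bone"),
        "Cerebellum": RoiShape(17, 29, 8, r, "brain"),
    }


@dataclass
class PhantomSpec:
    """Full description of one synthetic cohort."""

    n_patients: int = 15
    grid_shape: tuple[int, int, int] = (48, 48, 24)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    tissue_table: dict[str, tuple[float, float]] = field(
        default_factory=default_tissue_table
    )
    roi_layout: dict[str, RoiShape] = field(default_factory=default_roi_layout)
    body_semiaxes: tuple[float, float, float] = (20.0, 20.0, 11.0)
    gain_range: tuple[float, float] = (1.0, 1.0)
    offset_range: tuple[float, float] = (0.0, 0.0)
    bias_amplitude: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise SpecValidationError("a cohort needs >= 2 patients")
        if self.gain_range[0] <= 0:
            raise SpecValidationError("gain range lower bound must be > 0")
        for name, rng in (("gain", self.gain_range), ("offset", self.offset_range)):
            if rng[0] > rng[1]:
                raise SpecValidationError(f"{name}_range lo > hi: {rng}")
        if self.bias_amplitude < 0 or self.noise_sd < 0:
            raise SpecValidationError("bias_amplitude and noise_sd must be >= 0")
        for tissue, (mean, sd) in self.tissue_table.items():
            if mean < 0 or sd < 0:
                raise SpecValidationError(
                    f"tissue {tissue!r} has negative mean or SD"
                )
        missing = set(HEALTHY_TISSUE_ROIS) - set(self.roi_layout)
        if missing:
            raise SpecValidationError(f"roi_layout misses ROIs: {sorted(missing)}")
        nz = self.grid_shape[2]
        for name, shape in self.roi_layout.items():
            if shape.tissue not in self.tissue_table:
                raise SpecValidationError(
                    f"ROI {name!r} uses unknown tissue {shape.tissue!r}"
                )
            if shape.z_start < 0 or shape.z_start + shape.n_slices > nz:
                raise SpecValidationError(f"ROI {name!r} slices exceed the grid")


PRESET_NAMES = ("het_like", "hom_like")


def preset(name: str, seed: int = 0) -> PhantomSpec:
    """Named cohort presets emulating heterogeneous vs homogeneous acquisition.

    ``het_like``: gain U(0.5, 2), offset U(-50, 50), bias amplitude 0.2,
    noise SD 5 — every patient effectively on a different scanner/protocol.
    ``hom_like``: unit gain, zero offset, no bias, noise SD 2 — one
    protocol, small acquisition noise only. 15 patients each.
    """
    if name == "het_like":
        return PhantomSpec(
            gain_range=(0.5, 2.0),
            offset_range=(-50.0, 50.0),
            bias_amplitude=0.2,
            noise_sd=5.0,
            seed=seed,
        )
    if name == "hom_like":
        return PhantomSpec(
            gain_range=(1.0, 1.0),
            offset_range=(0.0, 0.0),
            bias_amplitude=0.0,
            noise_sd=2.0,
            seed=seed,
        )
    raise UnknownPresetError(
        f"unknown preset {name!r}; expected one of {PRESET_NAMES}"
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _body_mask(spec: PhantomSpec) -> np.ndarray:
    nr, nc, nz = spec.grid_shape
    center = ((nr - 1) / 2.0, (nc - 1) / 2.0, (nz - 1) / 2.0)
    rr, cc, kk = np.meshgrid(
        np.arange(nr), np.arange(nc), np.arange(nz), indexing="ij"
    )
    a, b, c = spec.body_semiaxes
    d2 = (
        ((rr - center[0]) / a) ** 2
        + ((cc - center[1]) / b) ** 2
        + ((kk - center[2]) / c) ** 2
    )
    return d2 <= 1.0


def _roi_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    nr, nc, nz = spec.grid_shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    masks = {}
    for name, shape in spec.roi_layout.items():
        disc = (rr - shape.center_row) ** 2 + (cc - shape.center_col) ** 2 <= (
            shape.radius**2
        )
        mask = np.zeros(spec.grid_shape, dtype=bool)
        for k in range(shape.z_start, shape.z_start + shape.n_slices):
            mask[:, :, k] = disc
        masks[name] = mask
    return masks


def _check_layout(masks: Mapping[str, np.ndarray], body: np.ndarray) -> None:
    total = np.zeros(body.shape, dtype=int)
    for name, mask in masks.items():
        if not mask.any():
            raise SpecValidationError(f"ROI {name!r} rasterizes to zero voxels")
        if np.any(mask & ~body):
            raise SpecValidationError(f"ROI {name!r} leaves the body ellipsoid")
        total += mask
    if total.max() > 1:
        raise SpecValidationError("ROI shapes overlap")


def _base_phantom(
    spec: PhantomSpec, body: np.ndarray, masks: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    base = np.full(spec.grid_shape, spec.tissue_table["background"][0])
    sd_map = np.full(spec.grid_shape, spec.tissue_table["background"][1])
    body_mean, body_sd = spec.tissue_table["muscle"]  # soft-tissue bulk
    base[body] = body_mean
    sd_map[body] = body_sd
    for name, shape in spec.roi_layout.items():
        mean, sd = spec.tissue_table[shape.tissue]
        base[masks[name]] = mean
        sd_map[masks[name]] = sd
    if np.any(sd_map > 0):
        base = base + rng.normal(0.0, 1.0, spec.grid_shape) * sd_map
    return base


def _bias_field(
    spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray | None:
    if spec.bias_amplitude == 0:
        return None
    nr, nc, nz = spec.grid_shape
    u = np.linspace(-1, 1, nr)[:, None, None]
    v = np.linspace(-1, 1, nc)[None, :, None]
    w = np.linspace(-1, 1, nz)[None, None, :]
    terms = [u, v, w, u**2, v**2, w**2, u * v, u * w, v * w]
    coeffs = rng.uniform(-1.0, 1.0, len(terms))
    poly = sum(c * t for c, t in zip(coeffs, terms))
    peak = np.abs(poly).max()
    if peak == 0:
        return None
    return 1.0 + spec.bias_amplitude * poly / peak


def generate_cohort(spec: PhantomSpec, label: str = "synthetic") -> Cohort:
    """Generate a deterministic phantom cohort from a validated spec.

    The ROI masks returned with each patient are the exact ground-truth
    shapes (no segmentation), and the external mask is the body ellipsoid.
    """
    spec.validate()
    body = _body_mask(spec)
    masks = _roi_masks(spec)
    _check_layout(masks, body)

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_patients + 1)
    base_rng = np.random.default_rng(streams[0])
    base = _base_phantom(spec, body, masks, base_rng)

    patients = []
    for i in range(spec.n_patients):
        rng = np.random.default_rng(streams[i + 1])
        gain = rng.uniform(*spec.gain_range)
        offset = rng.uniform(*spec.offset_range)
        bias = _bias_field(spec, rng)
        voxels = base if bias is None else bias * base
        voxels = gain * voxels + offset
        if spec.noise_sd > 0:
            voxels = voxels + rng.normal(0.0, spec.noise_sd, spec.grid_shape)

        pid = f"P{i + 1:02d}"
        volume = VolumeGrid(
            patient_id=pid,
            voxels=voxels,
            spacing=spec.spacing,
            series_meta={"gain": gain, "offset": offset},
        )
        patients.append(
            CohortImage(
                volume=volume,
                rois=ROISet(grid_ref=pid, masks=dict(masks), shape=spec.grid_shape),
                external_mask=body.copy(),
            )
        )
    return Cohort(label=label, patients=patients)


def with_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    """Copy of a spec with a different seed."""
    return replace(spec, seed=seed)
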