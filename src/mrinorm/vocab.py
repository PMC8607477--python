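"""Controlled vocabularies: ROI names and standardization method names.

The 14 healthy-tissue ROIs are contoured on T2-weighted head-and-neck images:
three cerebrospinal-fluid levels, the two cheek fat pads, three nape-fat
levels, neck fat, both masseters, the rectus capitis posterior major, skull
and cerebellum. ``External`` is reserved for the body (head-and-neck) mask.

The cheek-fat ROIs are excluded from consistency evaluation because they are
consumed as the reference tissue of the Fat standardization method; scoring
them would bias that method.
"""

from __future__ import annotations

#: The 14 contoured healthy-tissue ROI names.
HEALTHY_TISSUE_ROIS: tuple[str, ...] = (
    "CSF_inf",
    "CSF_mid",
    "CSF_sup",
    "Fat_L",
    "Fat_R",
    "NapeFat_inf",
    "NapeFat_mid",
    "NapeFat_sup",
    "NeckFat",
    "Masseter_L",
    "Masseter_R",
    "RCPM",
    "Skull",
    "Cerebellum",
)

#: Reserved name for the body (external) mask.
EXTERNAL_ROI = "External"

#: ROI names accepted by :class:`mrinorm.grid.ROISet`.
ALLOWED_ROIS: frozenset[str] = frozenset(HEALTHY_TISSUE_ROIS) | {EXTERNAL_ROI}

#: Reference ROIs of the Fat method, excluded from evaluation.
CHEEK_FAT_ROIS: tuple[str, str] = ("Fat_L", "Fat_R")

#: The 12 ROIs scored by the consistency metric.
EVALUATED_ROIS: tuple[str, ...] = tuple(
    r for r in HEALTHY_TISSUE_ROIS if r not in CHEEK_FAT_ROIS
)

#: Standardization method vocabulary, in canonical display order.
METHOD_NAMES: tuple[str, ...] = (
    "Original",
    "MinMax",
    "Z-All",
    "Z-External",
    "Fat",
    "Nyul",
)

#: Default scaling constant of the cheek-fat standardization method.
FAT_SCALE_DEFAULT: float = 350.0

#: Default Nyul landmark percentiles.
NYUL_PERCENTILES_DEFAULT: tuple[float, ...] = (
    1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99,
)


def check_method_name(name: str) -> str:
    """Validate a method name against the fixed vocabulary."""
    if name not in METHOD_NAMES:
        from .errors import ConfigError

        raise ConfigError(
            f"unknown standardization method {name!r}; "
            f"expected one of {', '.join(METHOD_NAMES)}"
        )
    return name
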