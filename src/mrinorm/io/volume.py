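"""Format-dispatching volume writer."""

from __future__ import annotations

import os
from pathlib import Path

from ..errors import UnsupportedFormatError
from ..grid import VolumeGrid
from .dicom import write_dicom_series
from .nifti import write_nifti

__all__ = ["write_volume"]


def write_volume(volume: VolumeGrid, path: os.PathLike, format: str = "nifti"):
    """Write ``volume`` to ``path`` as NIfTI (single file) or a DICOM series.

    Raises
    ------
    UnsupportedFormatError
        For a format other than ``nifti`` or ``dicom``.
    OSError
        Re-raised with the offending path in the message.
    """
    try:
        if format == "nifti":
            return write_nifti(volume, path)
        if format == "dicom":
            return write_dicom_series(volume, path)
    except OSError as exc:
        raise OSError(f"cannot write {format} output to {Path(path)}: {exc}") from exc
    raise UnsupportedFormatError(
        f"unsupported output format {format!r}; expected 'nifti' or 'dicom'"
    )
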