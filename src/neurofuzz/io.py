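"""NIfTI-1 and TSV input/output.

Volumes travel as NIfTI-1 (plain or gzipped), RAS+ identity affine by
default, time axis last, with the repetition time stored in the time-axis
``pixdim`` field.  Motion traces are 6-column TSV files (translations in mm,
rotations in degrees).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .alff import MOTION_COLUMNS, BoldSeries

__all__ = [
    "read_volume",
    "write_volume",
    "read_bold",
    "write_bold",
    "read_motion_tsv",
    "write_motion_tsv",
]


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with format context
        raise ValueError(
            f"{path} is not a readable NIfTI-1 file (.nii/.nii.gz): {exc}"
        ) from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise ValueError(f"{path}: expected NIfTI, got {type(img).__name__}")
    return img


def read_volume(path) -> np.ndarray:
    """Read a 2D/3D volume (labels or intensities) as an array."""
    return np.asanyarray(_load(path).dataobj)


def write_volume(data: np.ndarray, path, dtype=None) -> None:
    """Write an array as NIfTI-1 with an identity RAS+ affine."""
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    nib.save(img, str(path))


def read_bold(path, mask: np.ndarray | None = None) -> BoldSeries:
    """Read a 4D NIfTI as a BoldSeries; TR comes from the time pixdim."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got {data.ndim}D")
    tr = float(img.header["pixdim"][4])
    if tr <= 0:
        raise ValueError(f"{path}: repetition time missing from pixdim[4]")
    return BoldSeries(data, tr=tr, mask=mask)


def write_bold(series: BoldSeries, path) -> None:
    """Write a BoldSeries as 4D NIfTI-1 with TR in pixdim[4] (seconds)."""
    data = series.data
    if data.ndim == 3:  # (X, Y, T) -> (X, Y, 1, T)
        data = data[:, :, None, :]
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header["pixdim"][4] = series.tr
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_motion_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MOTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: motion TSV missing columns {sorted(missing)}")
    return df[list(MOTION_COLUMNS)]


def write_motion_tsv(trace: pd.DataFrame, path) -> None:
    trace[list(MOTION_COLUMNS)].to_csv(path, sep="\t", index=False)
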