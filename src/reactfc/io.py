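"""Volumetric image and event-table I/O with grid bookkeeping.

All volumes are carried as :class:`nibabel.Nifti1Image`; 4D images declare
their repetition time in the NIfTI header (pixdim[4], seconds). Two images
are considered to live on the same grid when their shapes match and their
affines agree elementwise within ``GRID_ATOL`` mm — anything looser must go
through :func:`resample_to_grid` explicitly.
"""

from __future__ import annotations

import os
import warnings

import nibabel as nib
import numpy as np
import pandas as pd
from nilearn.image import resample_img
from scipy import ndimage

#: Elementwise affine agreement (mm) below which two grids are "equal".
GRID_ATOL = 1e-4

#: The closed set of task outcome conditions modeled in the first level.
CONDITIONS = (
    "expected_reward",
    "unexpected_reward",
    "expected_punishment",
    "unexpected_punishment",
)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


def voxel_sizes(img: nib.Nifti1Image) -> np.ndarray:
    """Voxel edge lengths (mm) from the affine's linear part."""
    return np.sqrt((np.asarray(img.affine)[:3, :3] ** 2).sum(axis=0))


def same_grid(a: nib.Nifti1Image, b: nib.Nifti1Image, atol: float = GRID_ATOL) -> bool:
    return a.shape[:3] == b.shape[:3] and np.allclose(a.affine, b.affine, atol=atol)


def check_same_grid(a: nib.Nifti1Image, b: nib.Nifti1Image, what: str = "volumes") -> None:
    if not same_grid(a, b):
        raise GridMismatchError(
            f"{what} are not on the same grid (shape {a.shape[:3]} vs {b.shape[:3]}); "
            "resample explicitly with resample_to_grid"
        )


def as_image(values: np.ndarray, affine: np.ndarray, tr: float | None = None) -> nib.Nifti1Image:
    """Wrap an array as a NIfTI image; declares TR (s) for 4D data."""
    img = nib.Nifti1Image(np.asarray(values), np.asarray(affine, dtype=float))
    if values.ndim == 4:
        if values.shape[3] < 2:
            raise ValueError("4D volume must have at least 2 time points")
        zooms = list(img.header.get_zooms()[:3]) + [float(tr) if tr else 0.0]
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    return img


def get_tr(img: nib.Nifti1Image) -> float:
    """Repetition time in seconds from the header of a 4D image."""
    if len(img.shape) != 4:
        raise ValueError("repetition time is only defined for 4D images")
    return float(img.header.get_zooms()[3])


def read_volume(path: str | os.PathLike) -> nib.Nifti1Image:
    """Read a 3D or 4D NIfTI volume, forcing a full data load.

    Errors mention the offending path; a 4D image must carry >= 2 volumes.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise IOError(f"could not read NIfTI volume {path}: {exc}") from exc
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected a 3D or 4D volume, got ndim={data.ndim}")
    if data.ndim == 4 and data.shape[3] < 2:
        raise ValueError(f"{path}: 4D volume with fewer than 2 time points")
    if not np.all(np.isfinite(data)):
        warnings.warn(f"{path}: non-finite voxels present; they must fall outside any active mask",
                      RuntimeWarning, stacklevel=2)
    out = nib.Nifti1Image(data, img.affine, img.header)
    return out


def write_volume(img: nib.Nifti1Image, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1; values stored as float32 unless integral."""
    path = os.fspath(path)
    data = np.asanyarray(img.dataobj)
    declared = img.header.get_data_shape()
    if tuple(declared) != tuple(data.shape):
        raise ValueError(
            f"declared header shape {tuple(declared)} does not match data shape {tuple(data.shape)}"
        )
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    if not np.issubdtype(data.dtype, np.integer):
        img = nib.Nifti1Image(data.astype(np.float32), img.affine, img.header)
        img.header.set_data_dtype(np.float32)
    nib.save(img, path)


def resample_to_grid(
    img: nib.Nifti1Image,
    target_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    method: str = "trilinear",
) -> nib.Nifti1Image:
    """Resample a 3D volume onto a target grid.

    ``method`` is 'trilinear' or 'nearest'. Values are interpolated at the
    world coordinates of the target voxel centers.
    """
    if method not in ("trilinear", "nearest"):
        raise ValueError(f"unknown resampling method {method!r}")
    aff = np.asarray(target_affine, dtype=float)
    if abs(np.linalg.det(aff[:3, :3])) < 1e-12 or abs(np.linalg.det(np.asarray(img.affine)[:3, :3])) < 1e-12:
        raise ValueError("degenerate affine: linear part is not invertible")
    interp = "linear" if method == "trilinear" else "nearest"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = resample_img(
            img,
            target_affine=aff,
            target_shape=tuple(int(s) for s in target_shape),
            interpolation=interp,
            force_resample=True,
            copy_header=True,
        )
    return nib.Nifti1Image(np.asanyarray(out.dataobj), out.affine, out.header)


def gaussian_smooth(img: nib.Nifti1Image, fwhm_mm: float) -> nib.Nifti1Image:
    """Separable Gaussian smoothing with sigma = fwhm/(2*sqrt(2*ln 2)) per axis.

    Applied per volume for 4D inputs. The boundary replicates edge values,
    so constant volumes (and constant offsets) pass through unchanged; sums
    over impulses supported away from the edge are conserved.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    data = np.asanyarray(img.dataobj).astype(float)
    sigma_mm = fwhm_mm * FWHM_TO_SIGMA
    sigma_vox = sigma_mm / voxel_sizes(img)
    if data.ndim == 3:
        out = ndimage.gaussian_filter(data, sigma=sigma_vox, mode="nearest")
    else:
        out = ndimage.gaussian_filter(data, sigma=(*sigma_vox, 0.0), mode="nearest")
    return nib.Nifti1Image(out, img.affine, img.header)


def mask_array(mask: nib.Nifti1Image) -> np.ndarray:
    """Boolean membership array of a {0,1} mask volume."""
    return np.asanyarray(mask.dataobj) > 0.5


def extract_roi_mean(img: nib.Nifti1Image, roi: nib.Nifti1Image) -> float:
    """Arithmetic mean of a 3D map over the member voxels of an ROI mask."""
    check_same_grid(img, roi, "map and ROI")
    members = mask_array(roi)
    if not members.any():
        raise ValueError("ROI mask is empty")
    values = np.asanyarray(img.dataobj)[members]
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values inside the ROI")
    return float(values.mean())


def read_events(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BIDS-style events table (TSV: onset, duration, trial_type).

    Onsets must be non-negative, durations >= 0 and trial_type drawn from the
    closed outcome-condition set; an empty table (header only) is allowed.
    """
    path = os.fspath(path)
    events = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(events.columns):
        raise ValueError(f"{path}: events file must have columns {sorted(required)}")
    return validate_events(events, source=path)


def validate_events(events: pd.DataFrame, source: str = "<events>") -> pd.DataFrame:
    events = events.copy()
    if len(events):
        if (events["onset"] < 0).any():
            raise ValueError(f"{source}: negative onsets are not allowed")
        if (events["duration"] < 0).any():
            raise ValueError(f"{source}: negative durations are not allowed")
        unknown = set(events["trial_type"]) - set(CONDITIONS)
        if unknown:
            raise ValueError(
                f"{source}: unknown condition labels {sorted(unknown)}; "
                f"allowed labels are {list(CONDITIONS)}"
            )
    return events


def write_events(events: pd.DataFrame, path: str | os.PathLike) -> None:
    events.to_csv(path, sep="\t", index=False)
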