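"""Reference-region Gjedde-Patlak graphical analysis of dynamic PET.

For an irreversibly bound tracer, once the reversible compartments have
equilibrated the normalized tissue activity is linear in normalized
integrated reference activity,

    C_T(t)/C_ref(t) = ki * (int_0^t C_ref dtau)/C_ref(t) + V,

and the slope ki (min^-1) is the tracer influx rate relative to the
reference region (cerebellar grey matter for [18F]FDOPA). The fit window
defaults to 24-89 minutes; with the standard 24-frame schedule
(4x1, 3x2, 3x3, 14x5 min) that selects the 13 five-minute frames starting
at or after 24 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import extract_roi_mean, gaussian_smooth, mask_array

#: (count, duration_min) blocks of the standard 24-frame, 89-minute schedule.
DEFAULT_FRAME_BLOCKS = ((4, 1.0), (3, 2.0), (3, 3.0), (14, 5.0))


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered PET frame boundaries in seconds."""

    start_s: np.ndarray
    end_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        end = np.asarray(self.end_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "end_s", end)
        if start.shape != end.shape or start.ndim != 1 or start.size == 0:
            raise ValueError("schedule needs matching 1D start/end arrays")
        if np.any(end <= start):
            raise ValueError("every frame must end after it starts")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(start[1:] < end[:-1] - 1e-9):
            raise ValueError("frames overlap")

    def __len__(self) -> int:
        return self.start_s.size

    @property
    def start_min(self) -> np.ndarray:
        return self.start_s / 60.0

    @property
    def end_min(self) -> np.ndarray:
        return self.end_s / 60.0

    @property
    def mid_min(self) -> np.ndarray:
        """Frame mid-times in minutes."""
        return (self.start_s + self.end_s) / 2.0 / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return (self.end_s - self.start_s) / 60.0

    @classmethod
    def from_blocks(cls, blocks=DEFAULT_FRAME_BLOCKS) -> "FrameSchedule":
        """Build a contiguous schedule from (count, duration_min) blocks."""
        durations = np.concatenate([[d * 60.0] * int(n) for n, d in blocks])
        end = np.cumsum(durations)
        start = end - durations
        return cls(start_s=start, end_s=end)

    @classmethod
    def read_tsv(cls, path) -> "FrameSchedule":
        tab = pd.read_csv(path, sep="\t")
        if not {"frame_start_s", "frame_end_s"}.issubset(tab.columns):
            raise ValueError(f"{path}: schedule needs columns frame_start_s, frame_end_s")
        return cls(tab["frame_start_s"].to_numpy(), tab["frame_end_s"].to_numpy())

    def write_tsv(self, path) -> None:
        pd.DataFrame({"frame_start_s": self.start_s, "frame_end_s": self.end_s}).to_csv(
            path, sep="\t", index=False
        )


def frame_midtimes(schedule: FrameSchedule) -> np.ndarray:
    """Frame mid-times in minutes (validated by the schedule itself)."""
    return schedule.mid_min


def cumulative_integral(activity: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Integral of a TAC from time 0 to each frame mid-time (units x min).

    Trapezoidal between mid-times; the segment before the first mid-time uses
    the TAC linearly extrapolated to t = 0 (clipped at 0), which makes the
    rule exact for both constant and linear reference curves.
    """
    c = np.asarray(activity, dtype=float)
    t = schedule.mid_min
    if c.shape[-1] != t.size:
        raise ValueError("activity length does not match the frame schedule")
    if t.size >= 2:
        c0 = c[..., 0] - (c[..., 1] - c[..., 0]) / (t[1] - t[0]) * t[0]
        c0 = np.maximum(c0, 0.0)
    else:
        c0 = np.zeros(c.shape[:-1])
    out = np.empty_like(c)
    out[..., 0] = 0.5 * (c0 + c[..., 0]) * t[0]
    for k in range(1, t.size):
        out[..., k] = out[..., k - 1] + 0.5 * (c[..., k] + c[..., k - 1]) * (t[k] - t[k - 1])
    return out


@dataclass(frozen=True)
class KiResult:
    """Patlak fit: influx rate ki (min^-1), intercept, fit quality, window."""

    ki: float
    intercept: float
    r_squared: float
    frames_used: np.ndarray
    t_star: float
    t_end: float = field(default=np.inf)


def window_frames(schedule: FrameSchedule, t_star: float, t_end: float) -> np.ndarray:
    """Indices of frames fully inside [t_star, t_end] minutes.

    A frame belongs to the window iff its start >= t_star and its end <= t_end.
    """
    eps = 1e-9
    return np.nonzero(
        (schedule.start_min >= t_star - eps) & (schedule.end_min <= t_end + eps)
    )[0]


class PatlakModel(BaseEstimator):
    """Reference-region Patlak estimator.

    Parameters: fit window ``t_star``/``t_end`` (minutes) and optional
    frame-duration weighting of the line fit. Fitted attributes: ``ki_``,
    ``intercept_``, ``r_squared_``, ``frames_used_``.
    """

    def __init__(self, t_star: float = 24.0, t_end: float = 89.0, duration_weighted: bool = False):
        self.t_star = t_star
        self.t_end = t_end
        self.duration_weighted = duration_weighted

    def fit(self, target: np.ndarray, ref: np.ndarray, schedule: FrameSchedule):
        target = np.asarray(target, dtype=float)
        ref = np.asarray(ref, dtype=float)
        if target.shape != ref.shape or target.shape != (len(schedule),):
            raise ValueError("target and reference TACs must match the schedule length")
        used = window_frames(schedule, self.t_star, self.t_end)
        if used.size < 3:
            raise ValueError(
                f"only {used.size} frames in the {self.t_star}-{self.t_end} min window; need >= 3"
            )
        if np.any(ref[used] <= 0):
            raise ValueError("non-positive reference activity inside the fit window")
        cum = cumulative_integral(ref, schedule)
        x = cum[used] / ref[used]
        y = target[used] / ref[used]
        w = schedule.durations_min[used] if self.duration_weighted else np.ones(used.size)
        wsum = w.sum()
        xm, ym = (w * x).sum() / wsum, (w * y).sum() / wsum
        sxx = (w * (x - xm) ** 2).sum()
        sxy = (w * (x - xm) * (y - ym)).sum()
        slope = sxy / sxx
        intercept = ym - slope * xm
        ss_res = (w * (y - slope * x - intercept) ** 2).sum()
        ss_tot = (w * (y - ym) ** 2).sum()
        self.ki_ = float(slope)
        self.intercept_ = float(intercept)
        self.r_squared_ = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0
        self.frames_used_ = used
        return self

    def result(self) -> KiResult:
        return KiResult(
            ki=self.ki_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            frames_used=self.frames_used_,
            t_star=self.t_star,
            t_end=self.t_end,
        )


def patlak_fit(
    target: np.ndarray,
    ref: np.ndarray,
    schedule: FrameSchedule,
    t_star: float = 24.0,
    t_end: float = 89.0,
    duration_weighted: bool = False,
) -> KiResult:
    """OLS Patlak fit of one target TAC against a reference TAC."""
    model = PatlakModel(t_star=t_star, t_end=t_end, duration_weighted=duration_weighted)
    return model.fit(target, ref, schedule).result()


def ki_map(
    pet: nib.Nifti1Image,
    ref_mask: nib.Nifti1Image,
    schedule: FrameSchedule,
    t_star: float = 24.0,
    t_end: float = 89.0,
    smooth_fwhm_mm: float = 0.0,
    brain_mask: nib.Nifti1Image | None = None,
) -> nib.Nifti1Image:
    """Voxelwise Patlak influx-rate map against the reference-region mean TAC.

    The reference TAC is the framewise mean over ``ref_mask``. Voxels outside
    ``brain_mask`` (when given) are NaN. ``smooth_fwhm_mm`` > 0 smooths the
    resulting map (8 mm is the conventional choice for group analysis).
    """
    data = np.asanyarray(pet.dataobj).astype(float)
    if data.ndim != 4 or data.shape[3] != len(schedule):
        raise ValueError("PET series does not match the frame schedule")
    ref = mask_array(ref_mask)
    if ref.shape != data.shape[:3]:
        raise ValueError("reference mask grid does not match the PET series")
    if not ref.any():
        raise ValueError("reference-region mask is empty")
    ref_tac = data[ref, :].mean(axis=0)
    used = window_frames(schedule, t_star, t_end)
    if used.size < 3:
        raise ValueError("fewer than 3 frames in the Patlak window")
    if np.any(ref_tac[used] <= 0):
        raise ValueError("non-positive reference activity inside the fit window")

    # The Patlak abscissa is shared by every voxel, so the voxelwise slopes
    # reduce to one closed-form regression against a common x.
    x = cumulative_integral(ref_tac, schedule)[used] / ref_tac[used]
    Y = data[..., used] / ref_tac[used]
    xm = x.mean()
    sxx = ((x - xm) ** 2).sum()
    ym = Y.mean(axis=-1)
    slope = ((Y - ym[..., None]) * (x - xm)).sum(axis=-1) / sxx

    if brain_mask is not None:
        brain = mask_array(brain_mask)
        slope = np.where(brain, slope, np.nan)
    out = nib.Nifti1Image(slope, pet.affine)
    if smooth_fwhm_mm > 0:
        filled = nib.Nifti1Image(np.nan_to_num(slope, nan=0.0), pet.affine)
        sm = gaussian_smooth(filled, smooth_fwhm_mm)
        sm_data = np.asanyarray(sm.dataobj)
        if brain_mask is not None:
            sm_data = np.where(mask_array(brain_mask), sm_data, np.nan)
        out = nib.Nifti1Image(sm_data, pet.affine)
    return out


def subject_ki(
    pet: nib.Nifti1Image,
    ref_mask: nib.Nifti1Image,
    roi: nib.Nifti1Image,
    schedule: FrameSchedule,
    t_star: float = 24.0,
    t_end: float = 89.0,
    smooth_fwhm_mm: float = 0.0,
) -> float:
    """Mean influx rate over an ROI (ventral striatum in the real analysis)."""
    kmap = ki_map(
        pet, ref_mask, schedule, t_star=t_star, t_end=t_end, smooth_fwhm_mm=smooth_fwhm_mm
    )
    return extract_roi_mean(kmap, roi)
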