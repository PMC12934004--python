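"""Canonical hemodynamic response, task regressors and drift basis.

The canonical HRF is the usual difference of two gamma densities (response
peaking near 5 s, undershoot near 15 s). Outcome events have zero duration
and are modeled as impulses; events with positive duration are boxcars whose
convolution is integrated on a fine grid before sampling at scan times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONDITIONS


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma parameters (delays/dispersions in seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0


def double_gamma_hrf(t: np.ndarray, params: HrfParams = HrfParams()) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF at times t (seconds)."""
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(
        t, a=params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        a=params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    h = peak - under / params.peak_undershoot_ratio
    return np.where(t >= 0, h, 0.0)


def condition_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    tr: float,
    n_scans: int,
    params: HrfParams = HrfParams(),
    oversampling: int = 20,
) -> np.ndarray:
    """HRF-convolved regressor for one condition, sampled at scan times.

    Zero-duration events contribute ``hrf(t - onset)``; positive-duration
    events contribute the integral of the HRF over the event boxcar.
    An empty event list yields an all-zero column.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    scan_times = np.arange(n_scans) * tr
    if onsets.size == 0:
        return np.zeros(n_scans)
    dt = tr / oversampling
    t_max = n_scans * tr + 40.0  # HRF support past the last scan
    n_fine = int(np.ceil(t_max / dt)) + 1
    u = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / dt))
        if i0 >= n_fine:
            continue
        if dur <= 0:
            u[i0] += 1.0 / dt  # impulse: convolution yields hrf(t - onset)
        else:
            i1 = min(int(round((onset + dur) / dt)), n_fine - 1)
            u[i0 : i1 + 1] += 1.0
    h = double_gamma_hrf(np.arange(n_fine) * dt, params)
    conv = np.convolve(u, h)[:n_fine] * dt
    idx = np.round(scan_times / dt).astype(int)
    return conv[idx]


def condition_regressors(
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    params: HrfParams = HrfParams(),
    conditions: tuple[str, ...] = CONDITIONS,
    oversampling: int = 20,
) -> pd.DataFrame:
    """One HRF-convolved column per condition (zero column if no events)."""
    run_length = n_scans * tr
    if len(events) and (events["onset"] >= run_length).any():
        raise ValueError("event onsets beyond the run duration")
    cols = {}
    for cond in conditions:
        sel = events[events["trial_type"] == cond] if len(events) else events
        cols[cond] = condition_regressor(
            sel["onset"].to_numpy() if len(sel) else np.array([]),
            sel["duration"].to_numpy() if len(sel) else np.array([]),
            tr,
            n_scans,
            params,
            oversampling,
        )
    return pd.DataFrame(cols)


def n_drift_terms(n_scans: int, tr: float, cutoff_s: float) -> int:
    """Number of cosine drift terms (beyond the intercept) for a run."""
    return int(np.floor(2.0 * n_scans * tr / cutoff_s)) + 1


def dct_drift_basis(n_scans: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass drift basis for one run (no intercept column).

    Columns are cos(pi*k*(n + 1/2)/N) for k = 1..K with
    K = floor(2*N*TR/cutoff) + 1, unit-normalized.
    """
    if cutoff_s <= 0:
        raise ValueError("cutoff_s must be positive")
    n_terms = n_drift_terms(n_scans, tr, cutoff_s)
    n = np.arange(n_scans)
    basis = np.column_stack(
        [np.cos(np.pi * k * (n + 0.5) / n_scans) for k in range(1, n_terms + 1)]
    )
    return basis * np.sqrt(2.0 / n_scans)
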