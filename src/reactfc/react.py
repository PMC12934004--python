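"""Receptor-enriched dual regression: spatial filtering and the first-level GLM.

Stage 1 regresses, volume by volume, the spatially demeaned BOLD values over
the stage-1 mask on the spatially demeaned molecular templates, yielding one
target-enriched time series per template (all templates are solved jointly
when more than one is supplied). Stage 2 places the normalized target series,
their interactions with the HRF-convolved task-outcome regressors, a cosine
drift basis and run intercepts in a voxelwise GLM over the stage-2 mask; the
beta map of each target regressor is that target's density-enriched
functional connectivity map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .hrf import HrfParams, condition_regressors, dct_drift_basis
from .io import CONDITIONS, get_tr
from .templates import TemplateMap

logger = logging.getLogger(__name__)


@dataclass
class TargetTimeSeries:
    """Per-run target-enriched time series (T x K) with target names."""

    data: pd.DataFrame  # columns = target names
    run_id: str
    normalized: bool = False

    @property
    def n_scans(self) -> int:
        return len(self.data)

    @property
    def target_names(self) -> list[str]:
        return list(self.data.columns)


def _bold_array(bold) -> np.ndarray:
    if isinstance(bold, nib.Nifti1Image) or hasattr(bold, "dataobj"):
        return np.asanyarray(bold.dataobj)
    return np.asarray(bold)


class CollinearTemplatesError(ValueError):
    """The template matrix is (numerically) rank deficient over the mask."""


class ReactExtractor(BaseEstimator, TransformerMixin):
    """Stage-1 spatial regression as a transformer: BOLD runs -> time series.

    Parameters
    ----------
    templates : list of TemplateMap
        Rescaled templates acting as spatial regressors (solved jointly).
    mask : ndarray of bool
        Stage-1 analysis mask (template domains & grey matter & coverage).
    max_condition : float
        Condition-number bound on the demeaned template Gram matrix above
        which the joint solve is refused as non-identifiable.
    """

    def __init__(self, templates=None, mask=None, max_condition: float = 1e8):
        self.templates = templates
        self.mask = mask
        self.max_condition = max_condition

    def fit(self, X=None, y=None):
        if not self.templates:
            raise ValueError("ReactExtractor needs at least one template")
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise ValueError("stage-1 mask is empty")
        cols = []
        for t in self.templates:
            if not isinstance(t, TemplateMap):
                raise TypeError("templates must be TemplateMap instances")
            if not t.rescaled:
                raise ValueError(f"template {t.name!r} must be rescaled before extraction")
            cols.append(t.values[mask].astype(float))
        X_t = np.column_stack(cols)
        X_t = X_t - X_t.mean(axis=0)  # spatial demeaning == implicit intercept
        gram = X_t.T @ X_t
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > self.max_condition:
            r = np.corrcoef(X_t.T) if X_t.shape[1] > 1 else np.ones((1, 1))
            raise CollinearTemplatesError(
                "template matrix is rank deficient over the stage-1 mask; "
                f"pairwise spatial correlations:\n{np.array_str(r, precision=3)}"
            )
        self.mask_ = mask
        self.design_ = X_t
        self.pinv_ = np.linalg.solve(gram, X_t.T)  # K x V
        self.target_names_ = [t.name for t in self.templates]
        # Spatial collinearity diagnostics: VIF of each template against the
        # others over the mask. High values (overlapping density maps, e.g.
        # DAT vs SERT) mean the joint spatial solve is near-unidentifiable.
        if X_t.shape[1] > 1:
            corr = np.corrcoef(X_t.T)
            self.spatial_corr_ = corr
            self.spatial_vif_ = np.diag(np.linalg.inv(corr))
        else:
            self.spatial_corr_ = np.ones((1, 1))
            self.spatial_vif_ = np.ones(1)
        return self

    def transform(self, bold, run_id: str = "run-1") -> TargetTimeSeries:
        """Extract the T x K target-enriched series from one 4D BOLD run."""
        data = _bold_array(bold)
        if data.ndim != 4:
            raise ValueError("expected a 4D BOLD run")
        if data.shape[:3] != self.mask_.shape:
            raise ValueError("BOLD run and stage-1 mask are on different grids")
        Y = data[self.mask_, :].astype(float)  # V x T
        if not np.all(np.isfinite(Y)):
            raise ValueError("non-finite BOLD values inside the stage-1 mask")
        Y = Y - Y.mean(axis=0, keepdims=True)
        coef = self.pinv_ @ Y  # K x T
        df = pd.DataFrame(coef.T, columns=self.target_names_)
        return TargetTimeSeries(data=df, run_id=run_id, normalized=False)


def extract_target_timeseries(
    bold, templates: list[TemplateMap], mask: np.ndarray, run_id: str = "run-1"
) -> TargetTimeSeries:
    """Functional wrapper around :class:`ReactExtractor` for a single run."""
    return ReactExtractor(templates=templates, mask=mask).fit().transform(bold, run_id)


def normalize_timeseries(ts: TargetTimeSeries) -> TargetTimeSeries:
    """Standardize each target column to mean 0, sample sd 1 within the run."""
    out = {}
    for name in ts.data.columns:
        col = ts.data[name].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(
                f"target series {name!r} in run {ts.run_id!r} is constant; cannot normalize"
            )
        out[name] = (col - col.mean()) / sd
    return replace(ts, data=pd.DataFrame(out), normalized=True)


def build_interaction_regressors(
    ts: TargetTimeSeries, condition_regs: pd.DataFrame
) -> pd.DataFrame:
    """Elementwise products of each target series with each task regressor.

    Columns are named ``"<target>:<condition>"``; these capture event-locked
    modulations of the target-enriched signal.
    """
    if len(ts.data) != len(condition_regs):
        raise ValueError("target series and condition regressors differ in length")
    cols = {}
    for target in ts.data.columns:
        for cond in condition_regs.columns:
            cols[f"{target}:{cond}"] = (
                ts.data[target].to_numpy() * condition_regs[cond].to_numpy()
            )
    return pd.DataFrame(cols)


def build_first_level_design(
    ts_runs: list[TargetTimeSeries],
    condition_runs: list[pd.DataFrame],
    interaction_runs: list[pd.DataFrame] | None,
    tr: float,
    drift_cutoff_s: float | None = 128.0,
) -> pd.DataFrame:
    """Assemble the run-concatenated first-level design matrix.

    Condition, target and interaction columns are shared across runs
    (stacked); each run contributes its own cosine drift block and intercept.
    ``drift_cutoff_s=None`` omits the drift basis. Raises on rank
    deficiency, naming the most collinear column pair.
    """
    n_runs = len(ts_runs)
    if n_runs != len(condition_runs) or (
        interaction_runs is not None and n_runs != len(interaction_runs)
    ):
        raise ValueError("per-run component lists differ in length")
    run_ids = [ts.run_id for ts in ts_runs]
    if len(set(run_ids)) != n_runs:
        raise ValueError(f"run ids must be unique, got {run_ids}")
    blocks = []
    for r in range(n_runs):
        ts = ts_runs[r]
        if not ts.normalized:
            raise ValueError(f"target series for run {ts.run_id!r} must be normalized")
        parts = [
            condition_runs[r].reset_index(drop=True),
            ts.data.add_prefix("target_").reset_index(drop=True),
        ]
        if interaction_runs is not None:
            parts.append(interaction_runs[r].add_prefix("ix_").reset_index(drop=True))
        block = pd.concat(parts, axis=1)
        if len(set(map(len, [p for p in parts]))) != 1:
            raise ValueError(f"component lengths disagree in run {ts.run_id!r}")
        blocks.append(block)
    shared = pd.concat(blocks, axis=0, ignore_index=True)

    n_total = len(shared)
    drift_cols = {}
    intercept_cols = {}
    offset = 0
    for r in range(n_runs):
        n_scans = ts_runs[r].n_scans
        if drift_cutoff_s is not None:
            basis = dct_drift_basis(n_scans, tr, drift_cutoff_s)
            for k in range(basis.shape[1]):
                col = np.zeros(n_total)
                col[offset : offset + n_scans] = basis[:, k]
                drift_cols[f"drift_{ts_runs[r].run_id}_{k + 1}"] = col
        ic = np.zeros(n_total)
        ic[offset : offset + n_scans] = 1.0
        intercept_cols[f"intercept_{ts_runs[r].run_id}"] = ic
        offset += n_scans
    design = pd.concat(
        [shared, pd.DataFrame(drift_cols), pd.DataFrame(intercept_cols)], axis=1
    )

    X = design.to_numpy(dtype=float)
    # all-zero columns are allowed (a condition with no events); the rank
    # requirement applies to the columns that actually carry signal
    nonzero = np.linalg.norm(X, axis=0) > 0
    rank = np.linalg.matrix_rank(X[:, nonzero])
    if rank < int(nonzero.sum()):
        sd = X.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X.T)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValueError(
            f"first-level design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"most collinear pair: {design.columns[i]!r} and {design.columns[j]!r} "
            f"(r = {corr[i, j]:.4f}); columns with zero variance: "
            f"{[c for c, s in zip(design.columns, sd) if s == 0 and not c.startswith('intercept')]}"
        )
    return design


@dataclass
class FirstLevelResult:
    """Voxelwise OLS betas over the stage-2 mask, with residual variance."""

    design: pd.DataFrame
    betas: np.ndarray  # n_columns x n_mask_voxels
    residual_variance: np.ndarray  # n_mask_voxels
    df: int
    mask: np.ndarray
    affine: np.ndarray

    def beta_map(self, column: str) -> np.ndarray:
        """3D beta map for one design column (zero outside the mask)."""
        idx = list(self.design.columns).index(column)
        out = np.zeros(self.mask.shape)
        out[self.mask] = self.betas[idx]
        return out

    def beta_img(self, column: str) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.beta_map(column), self.affine)


def _ar1_whiten(M: np.ndarray, rho: float) -> np.ndarray:
    """Apply the AR(1) whitening filter along axis 0 of a run block."""
    out = M.astype(float).copy()
    out[1:] = M[1:] - rho * M[:-1]
    out[0] = M[0] * np.sqrt(1.0 - rho**2)
    return out


def fit_first_level(
    bold_runs: list,
    design: pd.DataFrame,
    mask: np.ndarray,
    affine: np.ndarray | None = None,
    whitening: str = "none",
) -> FirstLevelResult:
    """Voxelwise OLS of the concatenated BOLD runs on the design matrix.

    ``whitening='ar1'`` estimates a single lag-1 autocorrelation from the
    pooled OLS residuals, filters data and design per run, and refits.
    """
    mask = np.asarray(mask, dtype=bool)
    arrays = [_bold_array(b) for b in bold_runs]
    run_lengths = [a.shape[3] for a in arrays]
    if affine is None and hasattr(bold_runs[0], "affine"):
        affine = np.asarray(bold_runs[0].affine)
    if affine is None:
        affine = np.eye(4)
    Y = np.concatenate([a[mask, :].T for a in arrays], axis=0)  # T_total x V
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite BOLD values inside the stage-2 mask")
    X = design.to_numpy(dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("design rows do not match the total number of scans")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("fewer time points than design columns")

    def _ols(Xm, Ym):
        pinv = np.linalg.pinv(Xm)
        B = pinv @ Ym
        resid = Ym - Xm @ B
        return B, resid

    B, resid = _ols(X, Y)
    if whitening == "ar1":
        num = (resid[1:] * resid[:-1]).sum()
        den = (resid**2).sum()
        rho = float(num / den) if den > 0 else 0.0
        rho = float(np.clip(rho, -0.98, 0.98))
        Xw = np.empty_like(X)
        Yw = np.empty_like(Y)
        off = 0
        for n_scans in run_lengths:
            sl = slice(off, off + n_scans)
            Xw[sl] = _ar1_whiten(X[sl], rho)
            Yw[sl] = _ar1_whiten(Y[sl], rho)
            off += n_scans
        B, resid = _ols(Xw, Yw)
    elif whitening != "none":
        raise ValueError(f"unknown whitening mode {whitening!r}")

    rank = np.linalg.matrix_rank(X)
    df = Y.shape[0] - rank
    resid_var = (resid**2).sum(axis=0) / max(df, 1)
    return FirstLevelResult(
        design=design,
        betas=B,
        residual_variance=resid_var,
        df=df,
        mask=mask,
        affine=affine,
    )


def collinearity_diagnostics(design: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factors per design column.

    VIF_j = 1/(1 - R^2_j) with R^2_j from regressing column j on all other
    columns. Perfectly predictable columns report infinite VIF; columns with
    zero variance report NaN.
    """
    X = design.to_numpy(dtype=float)
    n_cols = X.shape[1]
    vifs = np.empty(n_cols)
    for j in range(n_cols):
        xj = X[:, j]
        sst = ((xj - xj.mean()) ** 2).sum()
        if sst == 0:
            vifs[j] = np.nan
            continue
        others = np.delete(X, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, xj, rcond=None)
        ssr = ((xj - others @ coef) ** 2).sum()
        r2 = 1.0 - ssr / sst
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.DataFrame({"column": design.columns, "vif": vifs}).set_index("column")


class FirstLevelGLM(BaseEstimator):
    """Stage-2 temporal regression for one subject-session.

    fit() takes the per-run BOLD images, event tables and (already extracted)
    target time series; it builds the design, fits the voxelwise GLM over the
    stage-2 mask and reports collinearity diagnostics.

    Fitted attributes: ``design_``, ``result_`` (:class:`FirstLevelResult`),
    ``vif_``, ``vif_warning_`` (True when any target/interaction VIF exceeds
    ``vif_warning_threshold``).
    """

    def __init__(
        self,
        hrf_params: HrfParams = HrfParams(),
        drift_cutoff_s: float = 128.0,
        whitening: str = "none",
        include_interactions: bool = True,
        vif_warning_threshold: float = 5.0,
    ):
        self.hrf_params = hrf_params
        self.drift_cutoff_s = drift_cutoff_s
        self.whitening = whitening
        self.include_interactions = include_interactions
        self.vif_warning_threshold = vif_warning_threshold

    def fit(self, bold_runs, events_runs, ts_runs, mask, tr: float | None = None):
        if tr is None:
            tr = get_tr(bold_runs[0])
        cond_runs = []
        ix_runs = [] if self.include_interactions else None
        norm_runs = []
        for bold, events, ts in zip(bold_runs, events_runs, ts_runs):
            n_scans = _bold_array(bold).shape[3]
            regs = condition_regressors(events, tr, n_scans, self.hrf_params)
            ts_n = ts if ts.normalized else normalize_timeseries(ts)
            cond_runs.append(regs)
            norm_runs.append(ts_n)
            if self.include_interactions:
                ix_runs.append(build_interaction_regressors(ts_n, regs))
        design = build_first_level_design(
            norm_runs, cond_runs, ix_runs, tr, self.drift_cutoff_s
        )
        affine = bold_runs[0].affine if hasattr(bold_runs[0], "affine") else None
        self.result_ = fit_first_level(
            bold_runs, design, mask, affine=affine, whitening=self.whitening
        )
        self.design_ = design
        self.vif_ = collinearity_diagnostics(design)
        of_interest = [
            c for c in design.columns if c.startswith("target_") or c.startswith("ix_")
        ]
        max_vif = np.nanmax(self.vif_.loc[of_interest, "vif"].to_numpy())
        self.max_target_vif_ = float(max_vif)
        self.vif_warning_ = bool(max_vif > self.vif_warning_threshold)
        if self.vif_warning_:
            msg = (
                f"design collinearity: max target/interaction VIF {max_vif:.1f} exceeds "
                f"{self.vif_warning_threshold}; joint estimation of overlapping "
                "templates is unreliable"
            )
            logger.warning(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        return self

    def connectivity_map(self, target_name: str) -> np.ndarray:
        return self.result_.beta_map(f"target_{target_name}")
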