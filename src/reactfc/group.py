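"""Group inference on drug-placebo contrasts of connectivity maps.

Within-subject drug minus placebo contrasts are analyzed with a one-sample
t-test (main drug effect) or with a mean-centered covariate model (does the
drug effect scale with dopamine synthesis capacity ki?). Suprathreshold
voxels at the cluster-forming threshold (p < 0.001 one-sided, each direction
separately) are grouped into connected components, and cluster extents are
assigned family-wise-error-corrected p-values against the permutation null
of the maximum cluster size (sign-flipping for the one-sample model,
Freedman-Lane residual permutation for the covariate model). The null pools
the maxima of both directions, so p_fwe < alpha controls the family-wise
rate at alpha over the whole two-sided family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats
from sklearn.base import BaseEstimator

#: Finite stand-in for a saturated t statistic (zero residual variance).
T_SATURATED = 1e12


@dataclass
class ConnectivityMap:
    """Per subject x session x target stage-2 beta map."""

    subject: str
    session: str  # "placebo" | "drug"
    target: str
    data: np.ndarray  # 3D
    model_mode: str = "single_target"


@dataclass
class ContrastMap:
    """Per-subject drug minus placebo connectivity difference."""

    subject: str
    target: str
    data: np.ndarray  # 3D


def session_contrast(drug: ConnectivityMap, placebo: ConnectivityMap) -> ContrastMap:
    """Voxelwise drug - placebo difference for one subject and target."""
    if drug.subject != placebo.subject:
        raise ValueError(
            f"subject mismatch: {drug.subject!r} (drug) vs {placebo.subject!r} (placebo)"
        )
    if drug.target != placebo.target:
        raise ValueError(f"target mismatch: {drug.target!r} vs {placebo.target!r}")
    if drug.data.shape != placebo.data.shape:
        raise ValueError("connectivity maps are on different grids")
    return ContrastMap(
        subject=drug.subject, target=drug.target, data=drug.data - placebo.data
    )


def _stack(contrasts) -> np.ndarray:
    if isinstance(contrasts, np.ndarray):
        return contrasts.astype(float)
    arrays = [c.data if isinstance(c, ContrastMap) else np.asarray(c) for c in contrasts]
    return np.stack(arrays).astype(float)


def group_t_map(
    contrasts, covariate: np.ndarray | None = None
) -> tuple[np.ndarray, int, np.ndarray]:
    """Voxelwise group t map.

    One-sample model: t = mean/(sd/sqrt(n)), df = n-1. Covariate model:
    t on the slope of contrast ~ 1 + centered covariate, df = n-2. Voxels
    with zero residual variance are saturated: t is set to a large finite
    sentinel and flagged in the returned boolean map.

    Returns (t_map, df, saturated_map).
    """
    Y = _stack(contrasts)
    n = Y.shape[0]
    if n < 3:
        raise ValueError("group models need at least 3 subjects")
    if covariate is None:
        m = Y.mean(axis=0)
        sd = Y.std(axis=0, ddof=1)
        df = n - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / (sd / np.sqrt(n))
        saturated = (sd == 0) & (m != 0)
        t = np.where(sd > 0, t, np.sign(m) * T_SATURATED)
        return np.nan_to_num(t, nan=0.0), df, saturated
    c = np.asarray(covariate, dtype=float)
    if c.shape != (n,):
        raise ValueError("covariate must have one value per subject")
    if c.std() == 0:
        raise ValueError("covariate is constant")
    ct = c - c.mean()
    sxx = (ct**2).sum()
    shape = Y.shape[1:]
    Yf = Y.reshape(n, -1)
    slope = (ct @ Yf) / sxx
    fitted = Yf.mean(axis=0) + np.outer(ct, slope)
    df = n - 2
    resid_ss = ((Yf - fitted) ** 2).sum(axis=0)
    resid_var = resid_ss / df
    # an exactly linear voxel leaves only rounding noise in the residuals
    tol = 1e-24 * np.maximum((Yf**2).sum(axis=0), np.finfo(float).tiny)
    degenerate = resid_ss <= tol
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(resid_var / sxx)
    saturated = degenerate & (slope != 0)
    t = np.where(~degenerate, t, np.sign(slope) * T_SATURATED)
    return (
        np.nan_to_num(t, nan=0.0).reshape(shape),
        df,
        saturated.reshape(shape),
    )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6, 18 or 26")


def threshold_clusters(
    tmap: np.ndarray,
    df: int,
    p_height: float = 0.001,
    direction: str = "pos",
    connectivity: int = 26,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Connected suprathreshold components in one direction.

    Voxels with one-sided p < p_height (t beyond the critical value in the
    requested direction) are labeled into connected components.

    Returns (labels, sizes): ``labels`` is 0 for sub-threshold voxels and
    1..n_clusters otherwise; ``sizes[i-1]`` is the extent of cluster i.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t_crit = stats.t.isf(p_height, df)
    if direction == "pos":
        supra = tmap > t_crit
    elif direction == "neg":
        supra = tmap < -t_crit
    else:
        raise ValueError("direction must be 'pos' or 'neg'")
    if mask is not None:
        supra &= np.asarray(mask, dtype=bool)
    labels, n_labels = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    sizes = (
        ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_labels + 1))
        .astype(int)
        if n_labels
        else np.array([], dtype=int)
    )
    return labels, sizes


def t_to_z(t: float, df: int) -> tuple[float, bool]:
    """Probability-matched conversion of a t statistic to a Z score.

    Works in log-probability space, so extreme but finite t values convert
    without underflow. A saturated t (zero residual variance) maps to a
    saturated Z, rendered "Inf" in reports.

    Returns (z, saturated).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if not np.isfinite(t) or abs(t) >= T_SATURATED:
        return float(np.sign(t)) * np.inf, True
    sign = 1.0 if t >= 0 else -1.0
    log_sf = stats.t.logsf(abs(t), df)
    z = -special.ndtri_exp(log_sf)
    return float(sign * z), False


def format_z(z: float, saturated: bool) -> str:
    return "Inf" if saturated or not np.isfinite(z) else f"{z:.4f}"


def _max_cluster_size(
    tmap: np.ndarray, t_crit: float, structure: np.ndarray, mask: np.ndarray | None
) -> int:
    best = 0
    for supra in (tmap > t_crit, tmap < -t_crit):
        if mask is not None:
            supra = supra & mask
        if not supra.any():
            continue
        labels, n_labels = ndimage.label(supra, structure=structure)
        if n_labels:
            sizes = np.bincount(labels.ravel())[1:]
            best = max(best, int(sizes.max()))
    return best


class PermutationClusterFWE(BaseEstimator):
    """Cluster-extent permutation test with FWE-corrected cluster p-values.

    Parameters
    ----------
    p_height : float
        One-sided cluster-forming threshold (default 0.001).
    n_perm : int
        Number of random permutations. For the one-sample model the full
        sign-flip set is enumerated instead whenever 2^n <= n_perm, which
        makes the p-values exact and independent of subject ordering.
    connectivity : int
        Voxel neighbourhood for cluster labeling: 6, 18 or 26 (default 26).
    random_state : int | numpy Generator | None
        Seed for the permutation draws.

    Fitted attributes: ``tmap_``, ``df_``, ``saturated_``, ``clusters_``
    (the cluster table), ``null_max_sizes_`` and ``exhaustive_``.
    """

    def __init__(
        self,
        p_height: float = 0.001,
        n_perm: int = 1000,
        connectivity: int = 26,
        random_state=None,
    ):
        self.p_height = p_height
        self.n_perm = n_perm
        self.connectivity = connectivity
        self.random_state = random_state

    def fit(self, contrasts, covariate=None, mask=None, affine=None):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        Y = _stack(contrasts)
        n = Y.shape[0]
        if n < 6:
            warnings.warn(
                f"only {n} subjects: the permutation null is coarse and the "
                "minimum attainable p-value large",
                RuntimeWarning,
                stacklevel=2,
            )
        mask = None if mask is None else np.asarray(mask, dtype=bool)
        affine = np.eye(4) if affine is None else np.asarray(affine)
        rng = np.random.default_rng(self.random_state)
        structure = _connectivity_structure(self.connectivity)

        tmap, df, saturated = group_t_map(Y, covariate)
        t_crit = stats.t.isf(self.p_height, df)

        shape = Y.shape[1:]
        Yf = Y.reshape(n, -1)
        if covariate is None:
            exhaustive = 2**n <= self.n_perm
            if exhaustive:
                signs_iter = (
                    np.array([1 if (i >> b) & 1 else -1 for b in range(n)])
                    for i in range(2**n)
                )
                null_max = np.fromiter(
                    (
                        _max_cluster_size(
                            self._one_sample_t(s[:, None] * Yf, n).reshape(shape),
                            t_crit,
                            structure,
                            mask,
                        )
                        for s in signs_iter
                    ),
                    dtype=int,
                    count=2**n,
                )
            else:
                null_max = np.empty(self.n_perm, dtype=int)
                for p in range(self.n_perm):
                    s = rng.choice([-1.0, 1.0], size=n)
                    t_p = self._one_sample_t(s[:, None] * Yf, n).reshape(shape)
                    null_max[p] = _max_cluster_size(t_p, t_crit, structure, mask)
        else:
            # Freedman-Lane: permute residuals of the reduced (intercept-only)
            # model, then re-test the covariate slope.
            exhaustive = False
            c = np.asarray(covariate, dtype=float)
            mean_y = Yf.mean(axis=0)
            resid = Yf - mean_y
            null_max = np.empty(self.n_perm, dtype=int)
            for p in range(self.n_perm):
                order = rng.permutation(n)
                Yp = mean_y + resid[order]
                t_p, _, _ = group_t_map(Yp.reshape((n,) + shape), c)
                null_max[p] = _max_cluster_size(t_p, t_crit, structure, mask)

        rows = []
        for direction in ("pos", "neg"):
            labels, sizes = threshold_clusters(
                tmap, df, self.p_height, direction, self.connectivity, mask
            )
            for lab in range(1, sizes.size + 1):
                in_cluster = labels == lab
                t_vals = np.where(in_cluster, np.abs(tmap), -np.inf)
                peak_idx = np.unravel_index(int(t_vals.argmax()), tmap.shape)
                peak_t = float(tmap[peak_idx])
                peak_sat = bool(saturated[peak_idx])
                z, z_sat = (np.inf, True) if peak_sat else t_to_z(peak_t, df)
                k = int(sizes[lab - 1])
                if exhaustive:
                    p_fwe = float((null_max >= k).mean())
                else:
                    p_fwe = float((1 + (null_max >= k).sum()) / (1 + self.n_perm))
                world = affine @ np.array([*peak_idx, 1.0])
                rows.append(
                    {
                        "direction": direction,
                        "peak_x_mm": world[0],
                        "peak_y_mm": world[1],
                        "peak_z_mm": world[2],
                        "peak_t": peak_t,
                        "peak_z_stat": z if not z_sat else np.sign(peak_t) * np.inf,
                        "saturated": z_sat,
                        "extent_k": k,
                        "p_fwe": p_fwe,
                    }
                )
        clusters = pd.DataFrame(
            rows,
            columns=[
                "direction",
                "peak_x_mm",
                "peak_y_mm",
                "peak_z_mm",
                "peak_t",
                "peak_z_stat",
                "saturated",
                "extent_k",
                "p_fwe",
            ],
        ).sort_values(["p_fwe", "extent_k"], ascending=[True, False], ignore_index=True)
        self.tmap_ = tmap
        self.df_ = df
        self.saturated_ = saturated
        self.clusters_ = clusters
        self.null_max_sizes_ = null_max
        self.exhaustive_ = exhaustive
        return self

    @staticmethod
    def _one_sample_t(Yf: np.ndarray, n: int) -> np.ndarray:
        m = Yf.mean(axis=0)
        sd = Yf.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / (sd / np.sqrt(n))
        return np.nan_to_num(np.where(sd > 0, t, np.sign(m) * T_SATURATED), nan=0.0)


def permutation_cluster_fwe(
    contrasts,
    covariate=None,
    p_height: float = 0.001,
    n_perm: int = 1000,
    seed=None,
    connectivity: int = 26,
    mask=None,
    affine=None,
) -> pd.DataFrame:
    """Functional wrapper returning the FWE cluster table."""
    est = PermutationClusterFWE(
        p_height=p_height, n_perm=n_perm, connectivity=connectivity, random_state=seed
    )
    est.fit(contrasts, covariate=covariate, mask=mask, affine=affine)
    return est.clusters_


def extract_cluster_effects(contrasts, cluster_mask: np.ndarray) -> np.ndarray:
    """Per-subject mean contrast over a cluster or ROI mask."""
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ValueError("cluster mask is empty")
    Y = _stack(contrasts)
    return Y[:, cluster_mask].mean(axis=1)


def roi_effect_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between two per-subject regional effects.

    Returns (r, two-sided p) with the p-value from the t distribution on
    n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1D effect vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("effects must be non-constant")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def write_cluster_table(clusters: pd.DataFrame, path) -> None:
    """Write a cluster table as TSV, rendering saturated Z as "Inf"."""
    out = clusters.copy()
    out["peak_z_stat"] = [
        format_z(z, s) for z, s in zip(out["peak_z_stat"], out["saturated"])
    ]
    out.drop(columns=["saturated"]).to_csv(path, sep="\t", index=False)
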