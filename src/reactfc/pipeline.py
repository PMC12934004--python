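"""End-to-end orchestration: simulate/load -> dual regression -> PET -> group.

`run_pipeline` consumes a :class:`~reactfc.synth.Cohort` (or an equivalent
object exposing the same accessors), runs the molecular target-enriched
connectivity analysis for every subject and session, quantifies each
subject's ki from dynamic PET, and performs the group inference
(one-sample drug effect and ki-covariate moderation) with permutation
cluster-level FWE correction, finishing with the regional effect
correlation against the emulated RPE drug effect.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .group import (
    ConnectivityMap,
    PermutationClusterFWE,
    extract_cluster_effects,
    roi_effect_correlation,
    session_contrast,
)
from .hrf import HrfParams
from .patlak import subject_ki
from .react import FirstLevelGLM, ReactExtractor
from .synth import SESSIONS, Cohort

logger = logging.getLogger(__name__)


@dataclass
class AnalysisOptions:
    """Analysis-side knobs (defaults are the pipeline's design choices)."""

    model_mode: str = "joint"  # "single_target" | "joint"
    drift_cutoff_s: float = 128.0
    whitening: str = "none"  # "none" | "ar1"
    include_interactions: bool = True
    hrf: HrfParams = field(default_factory=HrfParams)
    p_height: float = 0.001
    n_perm: int = 500
    connectivity: int = 26
    vif_warning_threshold: float = 5.0
    t_star_min: float = 24.0
    t_end_min: float = 89.0
    ki_smooth_fwhm_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.model_mode not in ("single_target", "joint"):
            raise ValueError("model_mode must be 'single_target' or 'joint'")
        if not (0 < self.p_height < 1):
            raise ValueError("p_height must lie in (0, 1)")


@dataclass
class PipelineResult:
    target_names: list
    connectivity: dict  # (subject_idx, session, target) -> 3D ndarray
    contrasts: dict  # target -> list[ContrastMap]
    ki_table: pd.DataFrame
    cluster_tables: dict  # target -> {"one_sample": df, "covariate": df}
    group_tmaps: dict  # target -> {"one_sample": ndarray, "covariate": ndarray}
    group_dfs: dict
    correlation: dict  # regional drug effect vs emulated RPE effect
    vif_max: float
    vif_warnings: list
    saturation_flags: int
    report: dict


def fit_subject_session(
    cohort: Cohort,
    subject: int,
    session: str,
    templates,
    amask,
    options: AnalysisOptions,
) -> dict:
    """Dual regression for one subject-session; returns {target: beta map}."""
    runs, events = cohort.session_runs(subject, session)
    tr = cohort.config.tr_s
    groups = (
        [templates] if options.model_mode == "joint" else [[t] for t in templates]
    )
    maps = {}
    vif_max = 0.0
    warned = []
    for group in groups:
        extractor = ReactExtractor(templates=group, mask=amask.stage1).fit()
        spatial_vif = float(np.max(extractor.spatial_vif_))
        vif_max = max(vif_max, spatial_vif)
        if spatial_vif > options.vif_warning_threshold:
            warned.append([t.name for t in group])
            logger.warning(
                "spatially collinear templates %s (max spatial VIF %.1f): joint "
                "estimation is unreliable",
                [t.name for t in group],
                spatial_vif,
            )
        ts_runs = [
            extractor.transform(run, run_id=f"run-{r + 1}")
            for r, run in enumerate(runs)
        ]
        glm = FirstLevelGLM(
            hrf_params=options.hrf,
            drift_cutoff_s=options.drift_cutoff_s,
            whitening=options.whitening,
            include_interactions=options.include_interactions,
            vif_warning_threshold=options.vif_warning_threshold,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            glm.fit(runs, events, ts_runs, amask.stage2, tr=tr)
        vif_max = max(vif_max, glm.max_target_vif_)
        if glm.vif_warning_:
            warned.append([t.name for t in group])
        for t in group:
            maps[t.name] = glm.connectivity_map(t.name)
    return {"maps": maps, "vif_max": vif_max, "vif_warnings": warned}


def run_pipeline(cohort: Cohort, options: AnalysisOptions | None = None) -> PipelineResult:
    options = options or AnalysisOptions()
    truth = cohort.truth
    cfg = cohort.config
    templates = cohort.prepared_templates()
    amask = cohort.analysis_mask()
    target_names = [t.name for t in templates]
    n = cfg.n_subjects

    connectivity = {}
    vif_max = 0.0
    vif_warnings = []
    for j in range(n):
        for session in SESSIONS:
            try:
                out = fit_subject_session(cohort, j, session, templates, amask, options)
            except Exception as exc:
                raise RuntimeError(
                    f"first-level stage failed for subject {truth.subject_ids[j]} "
                    f"session {session}: {exc}"
                ) from exc
            vif_max = max(vif_max, out["vif_max"])
            vif_warnings.extend(out["vif_warnings"])
            for name, beta in out["maps"].items():
                connectivity[(j, session, name)] = beta
        logger.info("first level done: %s", truth.subject_ids[j])

    contrasts = {
        name: [
            session_contrast(
                ConnectivityMap(truth.subject_ids[j], "drug", name,
                                connectivity[(j, "drug", name)], options.model_mode),
                ConnectivityMap(truth.subject_ids[j], "placebo", name,
                                connectivity[(j, "placebo", name)], options.model_mode),
            )
            for j in range(n)
        ]
        for name in target_names
    }

    ki_values = []
    for j in range(n):
        pet, ref_img, roi_img, schedule = cohort.pet(j)
        ki_values.append(
            subject_ki(
                pet, ref_img, roi_img, schedule,
                t_star=options.t_star_min, t_end=options.t_end_min,
                smooth_fwhm_mm=options.ki_smooth_fwhm_mm,
            )
        )
    ki_table = pd.DataFrame(
        {"subject_id": truth.subject_ids, "ki_cer": ki_values}
    )
    ki = np.asarray(ki_values)

    cluster_tables, group_tmaps, group_dfs = {}, {}, {}
    saturation_flags = 0
    rng_seed = np.random.SeedSequence(options.seed)
    for name in target_names:
        stack = np.stack([c.data for c in contrasts[name]])
        tables, tmaps, dfs = {}, {}, {}
        for kind, cov in (("one_sample", None), ("covariate", ki)):
            est = PermutationClusterFWE(
                p_height=options.p_height,
                n_perm=options.n_perm,
                connectivity=options.connectivity,
                random_state=np.random.default_rng(rng_seed.spawn(1)[0]),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                est.fit(stack, covariate=cov, mask=amask.stage2, affine=truth.affine)
            tables[kind] = est.clusters_
            tmaps[kind] = est.tmap_
            dfs[kind] = est.df_
            saturation_flags += int(est.clusters_["saturated"].sum())
        cluster_tables[name] = tables
        group_tmaps[name] = tmaps
        group_dfs[name] = dfs

    # Regional-effect correlation: mean drug effect in the top covariate
    # cluster of the first target vs the emulated RPE drug effect.
    correlation = {"r": float("nan"), "p": float("nan"), "cluster_extent": 0}
    first = target_names[0]
    cov_table = cluster_tables[first]["covariate"]
    if len(cov_table):
        best = cov_table.iloc[0]
        from .group import threshold_clusters

        labels, sizes = threshold_clusters(
            group_tmaps[first]["covariate"],
            group_dfs[first]["covariate"],
            options.p_height,
            str(best["direction"]),
            options.connectivity,
            mask=amask.stage2,
        )
        lab_sizes = list(sizes)
        lab = int(np.argmax(lab_sizes)) + 1 if lab_sizes else 0
        if lab:
            cluster_mask = labels == lab
            effects = extract_cluster_effects(
                np.stack([c.data for c in contrasts[first]]), cluster_mask
            )
            r, p = roi_effect_correlation(effects, truth.rpe_effect)
            r_ki, p_ki = roi_effect_correlation(effects, ki)
            correlation = {
                "r": r,
                "p": p,
                "r_vs_ki": r_ki,
                "p_vs_ki": p_ki,
                "cluster_extent": int(cluster_mask.sum()),
            }

    opts_dict = asdict(options)
    report = {
        "seed": options.seed,
        "n_subjects": n,
        "targets": target_names,
        "model_mode": options.model_mode,
        "options_hash": hashlib.sha256(
            json.dumps(opts_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "options": opts_dict,
        "max_target_vif": vif_max,
        "vif_warnings": vif_warnings,
        "saturated_cluster_peaks": saturation_flags,
    }
    return PipelineResult(
        target_names=target_names,
        connectivity=connectivity,
        contrasts=contrasts,
        ki_table=ki_table,
        cluster_tables=cluster_tables,
        group_tmaps=group_tmaps,
        group_dfs=group_dfs,
        correlation=correlation,
        vif_max=vif_max,
        vif_warnings=vif_warnings,
        saturation_flags=saturation_flags,
        report=report,
    )


def write_results(result: PipelineResult, cohort: Cohort, out_dir) -> None:
    """Persist connectivity maps, ki table, cluster tables and the run report."""
    from .group import write_cluster_table
    from .io import as_image, write_volume

    os.makedirs(out_dir, exist_ok=True)
    truth = cohort.truth
    conn_dir = os.path.join(out_dir, "connectivity")
    os.makedirs(conn_dir, exist_ok=True)
    for (j, session, name), beta in result.connectivity.items():
        sub = truth.subject_ids[j]
        write_volume(
            as_image(beta, truth.affine),
            os.path.join(conn_dir, f"{sub}_ses-{session}_target-{name}_beta.nii.gz"),
        )
    result.ki_table.to_csv(os.path.join(out_dir, "ki_cer.tsv"), sep="\t", index=False)
    for name, tables in result.cluster_tables.items():
        for kind, table in tables.items():
            write_cluster_table(
                table, os.path.join(out_dir, f"clusters_{name}_{kind}.tsv")
            )
    with open(os.path.join(out_dir, "correlation.json"), "w") as fh:
        json.dump(result.correlation, fh, indent=2)
    import nibabel  # noqa: F401  (version stamped below)
    import scipy

    report = dict(result.report)
    report["versions"] = {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "nibabel": nibabel.__version__,
    }
    with open(os.path.join(out_dir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
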