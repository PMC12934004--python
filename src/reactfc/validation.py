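"""Ground-truth recovery studies: the package's own validation experiments.

Each function runs one self-contained study against the synthetic cohort
generator and returns plain scalars: oracle equivalence of the two
regression stages, exact generative inversion at zero noise, recovery and
cluster detection at the default noise level, permutation-FWE calibration
under the null, covariate-moderation recovery, Patlak accuracy, and the
template-collinearity diagnostic. They are used by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats

from .group import (
    PermutationClusterFWE,
    extract_cluster_effects,
    group_t_map,
    roi_effect_correlation,
    threshold_clusters,
)
from .patlak import (
    DEFAULT_FRAME_BLOCKS,
    FrameSchedule,
    PatlakModel,
    cumulative_integral,
    subject_ki,
    window_frames,
)
from .react import (
    FirstLevelGLM,
    ReactExtractor,
    collinearity_diagnostics,
    extract_target_timeseries,
    fit_first_level,
)
from .synth import (
    SESSIONS,
    SynthConfig,
    build_cohort_truth,
    simulate_cohort,
    simulate_group_contrasts,
    simulate_pet,
)
from .templates import TemplateMap, template_spatial_correlation


def _derive_seed(seed: int, offset: int) -> int:
    return int((seed * 1_000 + offset) % (2**31 - 1))


# ---------------------------------------------------------------------------
# Stage-1/stage-2 oracle equivalence on a tiny random fixture
# ---------------------------------------------------------------------------

def stage_oracle_errors(seed: int = 0) -> dict:
    """Max |difference| between both regression stages and independent
    normal-equation / pseudo-inverse solves on a 60-voxel, 12-scan fixture."""
    import nibabel as nib
    import pandas as pd

    rng = np.random.default_rng(_derive_seed(seed, 1))
    shape = (5, 4, 3)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    mask = np.ones(shape, bool)
    x1, x2 = rng.random(shape), rng.random(shape)
    empty_ref = np.zeros(shape, bool)
    templates = [
        TemplateMap("a", nib.Nifti1Image(x1, affine), mask.copy(),
                    reference_mask=empty_ref, rescaled=True),
        TemplateMap("b", nib.Nifti1Image(x2, affine), mask.copy(),
                    reference_mask=empty_ref.copy(), rescaled=True),
    ]
    data = rng.standard_normal(shape + (12,))
    bold = nib.Nifti1Image(data, affine)
    ts = extract_target_timeseries(bold, templates, mask)
    X = np.column_stack([x1.ravel(), x2.ravel()])
    X = X - X.mean(axis=0)
    Y = data.reshape(-1, 12)
    Y = Y - Y.mean(axis=0)
    oracle = np.linalg.inv(X.T @ X) @ X.T @ Y  # K x T
    err1 = float(np.abs(ts.data.to_numpy() - oracle.T).max())

    design = pd.DataFrame(
        rng.standard_normal((12, 4)), columns=["c0", "c1", "c2", "c3"]
    )
    res = fit_first_level([bold], design, mask)
    pinv = np.linalg.pinv(design.to_numpy())
    oracle2 = pinv @ data.reshape(-1, 12).T
    err2 = float(np.abs(res.betas - oracle2).max())
    return {"stage1_max_abs_err": err1, "stage2_max_abs_err": err2, "n_voxels": 60}


# ---------------------------------------------------------------------------
# Generative inversion at zero noise
# ---------------------------------------------------------------------------

def _session_glm(cohort, subject, session, templates, amask):
    runs, events = cohort.session_runs(subject, session)
    ex = ReactExtractor(templates=templates, mask=amask.stage1).fit()
    ts = [ex.transform(r, run_id=f"run-{i + 1}") for i, r in enumerate(runs)]
    glm = FirstLevelGLM()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        glm.fit(runs, events, ts, amask.stage2, tr=cohort.config.tr_s)
    return glm


def zero_noise_inversion(seed: int = 0, n_subjects: int = 16) -> dict:
    """At zero noise every pipeline estimate equals its generating value."""
    cfg = SynthConfig(
        n_subjects=n_subjects, snr=math.inf, pet_noise_frac=0.0,
        seed=_derive_seed(seed, 2),
    )
    cohort = simulate_cohort(cfg)
    truth = cohort.truth
    templates = cohort.prepared_templates()
    amask = cohort.analysis_mask()
    m2 = amask.stage2
    d = truth.ki - truth.ki_sample_mean

    coupling_err = delta_err = gain_err = 0.0
    ix_col = "ix_target0:unexpected_reward"
    support = truth.interaction_support[0]
    for j in range(cfg.n_subjects):
        glm_p = _session_glm(cohort, j, "placebo", templates, amask)
        glm_d = _session_glm(cohort, j, "drug", templates, amask)
        for k, name in enumerate(truth.target_names):
            beta = glm_p.connectivity_map(name)
            coupling_err = max(
                coupling_err, float(np.abs(beta - truth.coupling[k])[m2].max())
            )
            contrast = glm_d.connectivity_map(name) - beta
            expected = truth.delta[k] * (1.0 + truth.gamma[k] * d[j])
            delta_err = max(delta_err, float(np.abs(contrast - expected)[m2].max()))
        ix_beta = glm_p.result_.beta_map(ix_col)
        g_hat = float(
            (ix_beta[m2] * support[m2]).sum() / (support[m2] ** 2).sum()
        )
        gain_err = max(gain_err, abs(g_hat - truth.interaction_gain[0, 1]))

    ki_err = intercept_err = 0.0
    for j in range(cfg.n_subjects):
        pet, ref, roi, sched = cohort.pet(j)
        ki_err = max(ki_err, abs(subject_ki(pet, ref, roi, sched) - truth.ki[j]))
        data = np.asanyarray(pet.dataobj)
        roi_tac = data[np.asanyarray(roi.dataobj) > 0.5].mean(axis=0)
        ref_tac = data[np.asanyarray(ref.dataobj) > 0.5].mean(axis=0)
        model = PatlakModel().fit(roi_tac, ref_tac, sched)
        intercept_err = max(
            intercept_err, abs(model.intercept_ - cfg.pet_blood_volume)
        )
    return {
        "coupling_max_abs_err": coupling_err,
        "drug_shift_max_abs_err": delta_err,
        "interaction_gain_max_abs_err": gain_err,
        "patlak_ki_max_abs_err": ki_err,
        "patlak_intercept_max_abs_err": intercept_err,
        "n_subjects": cfg.n_subjects,
    }


# ---------------------------------------------------------------------------
# Recovery and cluster detection at the default noise level
# ---------------------------------------------------------------------------

def latent_recovery(seed: int = 0, n_subjects: int = 10) -> dict:
    """Mean correlation between extracted and true latent target series at
    the default SNR, averaged over subjects."""
    cfg = SynthConfig(n_subjects=n_subjects, seed=_derive_seed(seed, 3))
    cohort = simulate_cohort(cfg)
    templates = cohort.prepared_templates()
    amask = cohort.analysis_mask()
    ex = ReactExtractor(templates=templates, mask=amask.stage1).fit()
    rs = []
    for j in range(n_subjects):
        runs, _ = cohort.session_runs(j, "placebo")
        ts = ex.transform(runs[0], run_id="run-1").data.to_numpy()
        s = cohort.latent_series(j, "placebo", 0)
        for k in range(cfg.n_targets):
            rs.append(float(np.corrcoef(ts[:, k], s[:, k])[0, 1]))
    return {"latent_recovery_r_mean": float(np.mean(rs)),
            "latent_recovery_r_min": float(np.min(rs)), "n_subjects": n_subjects}


def _cohort_detected(cfg: SynthConfig, n_perm: int, perm_seed: int) -> bool:
    """Full pipeline for one cohort: does the drug-effect cluster survive
    FWE at 0.05 on the first target?"""
    cohort = simulate_cohort(cfg)
    templates = cohort.prepared_templates()
    amask = cohort.analysis_mask()
    name = cohort.truth.target_names[0]
    contrasts = []
    for j in range(cfg.n_subjects):
        glm_p = _session_glm(cohort, j, "placebo", templates, amask)
        glm_d = _session_glm(cohort, j, "drug", templates, amask)
        contrasts.append(glm_d.connectivity_map(name) - glm_p.connectivity_map(name))
    est = PermutationClusterFWE(n_perm=n_perm, random_state=perm_seed)
    est.fit(np.stack(contrasts), mask=amask.stage2, affine=cohort.truth.affine)
    return bool(len(est.clusters_) and (est.clusters_["p_fwe"] < 0.05).any())


def drug_effect_detection(
    seed: int = 0, n_cohorts: int = 20, n_perm: int = 500
) -> dict:
    """Detection rate of the generated drug effect across seeded cohorts,
    and the false-detection rate across matched null cohorts."""
    hits = null_hits = 0
    for c in range(n_cohorts):
        cfg = SynthConfig(seed=_derive_seed(seed, 10 + c))
        hits += _cohort_detected(cfg, n_perm, _derive_seed(seed, 300 + c))
        null_cfg = SynthConfig(delta_scale=0.0, seed=_derive_seed(seed, 10 + c))
        null_hits += _cohort_detected(null_cfg, n_perm, _derive_seed(seed, 400 + c))
    return {
        "detection_rate": hits / n_cohorts,
        "null_detection_rate": null_hits / n_cohorts,
        "n_cohorts": n_cohorts,
    }


# ---------------------------------------------------------------------------
# FWE calibration under the null
# ---------------------------------------------------------------------------

def fwe_calibration(
    seed: int = 0, n_cohorts: int = 200, n_perm: int = 500, n_subjects: int = 16
) -> dict:
    """Family-wise false-positive rate at nominal 0.05 over null cohorts,
    with the exact (Clopper-Pearson) binomial 95% interval around 0.05."""
    truth = build_cohort_truth(SynthConfig(seed=_derive_seed(seed, 4)))
    mask = truth.brain
    rng = np.random.default_rng(_derive_seed(seed, 5))
    hits = 0
    for c in range(n_cohorts):
        Y = simulate_group_contrasts(n_subjects, mask, rng)
        est = PermutationClusterFWE(n_perm=n_perm, random_state=rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est.fit(Y, mask=mask, affine=truth.affine)
        hits += bool(len(est.clusters_) and (est.clusters_["p_fwe"] < 0.05).any())
    # exact binomial 95% acceptance band for a true rate of 0.05
    k = np.arange(n_cohorts + 1)
    cdf = stats.binom.cdf(k, n_cohorts, 0.05)
    k_lo = int(k[np.searchsorted(cdf, 0.025)])
    k_hi = int(k[np.searchsorted(cdf, 0.975)])
    return {
        "fwe_rate": hits / n_cohorts,
        "band_low": k_lo / n_cohorts,
        "band_high": k_hi / n_cohorts,
        "n_cohorts": n_cohorts,
    }


# ---------------------------------------------------------------------------
# Covariate moderation recovery
# ---------------------------------------------------------------------------

def covariate_moderation(seed: int = 0, n_cohorts: int = 50) -> dict:
    """With gamma > 0 the covariate t-map localizes to the drug-effect mask
    and the cluster-mean drug effect correlates positively with true ki and
    with the emulated RPE drug effect."""
    cfg = SynthConfig(seed=_derive_seed(seed, 6))
    truth = build_cohort_truth(cfg)
    mask = truth.brain
    delta = truth.delta[0]
    support = delta > 0.1 * delta.max()
    core = truth.effect_mask[0]
    rng = np.random.default_rng(_derive_seed(seed, 7))
    loc = cor_ki = cor_rpe = 0
    n = cfg.n_subjects
    for c in range(n_cohorts):
        ki = np.abs(rng.normal(cfg.ki_mean, cfg.ki_sd, n))
        Y = simulate_group_contrasts(
            n, mask, rng, delta_map=delta, ki=ki, gamma=truth.gamma[0]
        )
        rpe = cfg.rpe_lambda * (ki - ki.mean()) + rng.normal(
            0, cfg.rpe_noise_frac * cfg.rpe_lambda * cfg.ki_sd, n
        )
        tmap, df, _ = group_t_map(Y, covariate=ki)
        peak = np.unravel_index(int(tmap.argmax()), tmap.shape)
        labels, sizes = threshold_clusters(tmap, df, 0.001, "pos", mask=mask)
        if not sizes.size:
            continue
        cluster = labels == (int(np.argmax(sizes)) + 1)
        covered = (cluster & core).sum() / core.sum()
        loc += bool(support[peak] and covered > 0.5)
        eff = extract_cluster_effects(Y, cluster)
        r1, p1 = roi_effect_correlation(eff, ki)
        r2, p2 = roi_effect_correlation(eff, rpe)
        cor_ki += bool(r1 > 0 and p1 < 0.05)
        cor_rpe += bool(r2 > 0 and p2 < 0.05)
    return {
        "localization_rate": loc / n_cohorts,
        "ki_correlation_rate": cor_ki / n_cohorts,
        "rpe_correlation_rate": cor_rpe / n_cohorts,
        "n_cohorts": n_cohorts,
    }


# ---------------------------------------------------------------------------
# Patlak accuracy
# ---------------------------------------------------------------------------

def patlak_validation(seed: int = 0, n_reps: int = 500) -> dict:
    schedule = FrameSchedule.from_blocks(DEFAULT_FRAME_BLOCKS)
    t = schedule.mid_min
    ref = (t / 10.0) ** 1.5 * np.exp(-t / 10.0) + 0.3 * (1 - np.exp(-t / 10.0))
    ref = ref / ref.max()
    cum = cumulative_integral(ref, schedule)
    true_ki, v = 0.010, 0.4
    clean = true_ki * cum + v * ref
    model = PatlakModel().fit(clean, ref, schedule)
    noiseless_err = abs(model.ki_ - true_ki)
    intercept_err = abs(model.intercept_ - v)

    rng = np.random.default_rng(_derive_seed(seed, 8))
    noise_sd = 0.05 * clean.max()
    estimates = [
        PatlakModel().fit(clean + rng.normal(0, noise_sd, clean.shape), ref, schedule).ki_
        for _ in range(n_reps)
    ]
    bias_pct = 100.0 * (float(np.mean(estimates)) - true_ki) / true_ki
    used = window_frames(schedule, 24.0, 89.0)
    return {
        "noiseless_ki_abs_err": noiseless_err,
        "noiseless_intercept_abs_err": intercept_err,
        "mc_bias_pct": bias_pct,
        "frames_in_window": int(used.size),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Template collinearity diagnostic
# ---------------------------------------------------------------------------

def collinearity_study(seed: int = 0, rho: float = 0.9) -> dict:
    """Overlapping templates: pairwise spatial r and the joint-model VIF."""
    cfg = SynthConfig(rho=rho, seed=_derive_seed(seed, 9))
    cohort = simulate_cohort(cfg)
    templates = cohort.prepared_templates()
    amask = cohort.analysis_mask()
    r = template_spatial_correlation(templates, amask.stage1)
    ex = ReactExtractor(templates=templates, mask=amask.stage1).fit()
    glm = _session_glm(cohort, 0, "placebo", templates, amask)
    vif = collinearity_diagnostics(glm.design_)
    return {
        "template_pairwise_r": float(r.iloc[0, 1]),
        "spatial_vif_max": float(ex.spatial_vif_.max()),
        "temporal_vif_max": float(
            vif.loc[[c for c in glm.design_.columns if c.startswith(("target_", "ix_"))],
                    "vif"].max()
        ),
    }
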