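"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator is the algebraic inverse of the analysis: per session the BOLD
signal is a sum of template-shaped coupling maps times latent target time
series, HRF-convolved task-outcome responses, event-locked interaction
terms, cosine drifts and AR(1) spatio-temporally correlated noise. In the
drug session the coupling of each target gains a shift map whose magnitude
scales with the subject's dopamine synthesis capacity ki, and the same ki
drives the simulated PET time-activity curves — so the end-to-end loop
(BOLD drug effect moderated by PET-measured ki) is closed by construction.

Task-activation, drug-shift and interaction-support maps are orthogonalized
against the templates (and the spatial mean) over the stage-1 voxels, and
drifts live inside the analysis drift span; at zero noise every pipeline
estimate therefore equals its generating parameter exactly.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .hrf import HrfParams, condition_regressors, dct_drift_basis
from .io import CONDITIONS, FWHM_TO_SIGMA, as_image, write_events, write_volume
from .patlak import DEFAULT_FRAME_BLOCKS, FrameSchedule, cumulative_integral
from .templates import (
    AnalysisMask,
    TemplateMap,
    build_analysis_mask,
    prepare_template,
    template_from_img,
)

SESSIONS = ("placebo", "drug")


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the real design: two sessions (placebo, drug), 3 task
    runs of 120 scans at TR 2.32 s per session, n = 16 subjects, the
    24-frame PET schedule, and ki drawn from N(0.010, 0.002) min^-1
    (truncated positive), a plausible [18F]FDOPA scale.
    """

    shape: tuple = (20, 20, 12)
    voxel_size_mm: float = 2.0
    n_subjects: int = 16
    n_targets: int = 2
    rho: float = 0.0  # template overlap: shared-blob weight in [0, 1)
    blob_sigma_vox: float = 0.0  # template blob width; 0 -> min(shape)/7
    runs_per_session: int = 3
    scans_per_run: int = 120
    tr_s: float = 2.32
    events_per_condition_per_run: int = 3
    min_event_spacing_s: float = 8.0
    coupling_amplitude: float = 1.0  # BOLD units per unit latent series
    task_amplitude: float = 0.5
    delta_scale: float = 0.5  # drug-shift peak, fraction of coupling_amplitude
    gamma: float = 100.0  # ki moderation (per min^-1), applied to target 0
    interaction_gain: float = 0.3  # (target 0, unexpected_reward)
    snr: float = 1.0  # signal sd / noise sd; math.inf -> noiseless
    ar_coef: float = 0.3
    noise_smooth_fwhm_mm: float = 4.0
    drift_amplitude: float = 0.2
    drift_cutoff_s: float = 128.0
    ki_mean: float = 0.010
    ki_sd: float = 0.002
    pet_blood_volume: float = 0.4
    pet_noise_frac: float = 0.05  # frame noise sd as fraction of peak activity
    frame_blocks: tuple = DEFAULT_FRAME_BLOCKS
    rpe_lambda: float = 1.0
    rpe_noise_frac: float = 0.7  # noise sd as fraction of lambda*ki_sd
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if min(self.shape) < 8:
            raise ValueError("grid too small for the template blobs (need >= 8 per axis)")
        for name in ("voxel_size_mm", "tr_s", "snr", "ki_mean", "ki_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scans_per_run < 8 or self.runs_per_session < 1:
            raise ValueError("need at least 1 run of >= 8 scans")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -np.asarray(self.shape) / 2.0 * self.voxel_size_mm
        return aff

    @property
    def schedule(self) -> FrameSchedule:
        return FrameSchedule.from_blocks(self.frame_blocks)


def _rng(config: SynthConfig, *key) -> np.random.Generator:
    """Deterministic generator for one (subject, session, run, stream) slot."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _blob(shape, center, sigma) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-d2 / (2.0 * sigma**2))


def _ellipsoid(shape, scale=1.0) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    center = [(s - 1) / 2.0 for s in shape]
    radii = [max(s / 2.0 - 1.0, 2.0) * scale for s in shape]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d2 <= 1.0


def _frac_center(shape, fx, fy, fz):
    return (fx * (shape[0] - 1), fy * (shape[1] - 1), fz * (shape[2] - 1))


@dataclass
class CohortTruth:
    """Everything needed to reconstruct and score a synthetic cohort."""

    config: SynthConfig
    affine: np.ndarray
    target_names: list
    templates_raw: np.ndarray  # K x shape, pre-masking density maps
    reference_masks: np.ndarray  # K x shape bool
    grey: np.ndarray
    brain: np.ndarray
    coupling: np.ndarray  # K x shape: base coupling maps B_k
    delta: np.ndarray  # K x shape: drug shift maps
    effect_mask: np.ndarray  # K x shape bool: core of each delta blob
    task_maps: np.ndarray  # 4 x shape
    interaction_support: np.ndarray  # K x shape
    interaction_gain: np.ndarray  # K x 4
    gamma: np.ndarray  # per target
    ki: np.ndarray  # per subject (min^-1)
    rpe_effect: np.ndarray  # per subject emulated regional RPE drug effect
    pet_roi: np.ndarray  # shape bool, ventral-striatum analogue
    pet_reference: np.ndarray  # shape bool, cerebellar-reference analogue
    pet_ki_map: np.ndarray | None = None  # base spatial ki pattern (ROI overridden)
    subject_ids: list = field(default_factory=list)

    @property
    def ki_sample_mean(self) -> float:
        return float(self.ki.mean())


class Cohort:
    """A lazily generated synthetic cohort.

    Volumes are regenerated deterministically from the master seed on every
    access, so a full cohort never needs to be held in memory at once.
    """

    def __init__(self, truth: CohortTruth):
        self.truth = truth
        self.config = truth.config

    # -- study-level artifacts -------------------------------------------
    def template_maps(self) -> list[TemplateMap]:
        """Raw templates (domain = brain, with their reference masks)."""
        t = self.truth
        out = []
        for k, name in enumerate(t.target_names):
            img = as_image(t.templates_raw[k], t.affine)
            out.append(
                TemplateMap(
                    name=name,
                    img=img,
                    domain=t.brain.copy(),
                    reference_mask=t.reference_masks[k].copy(),
                )
            )
        return out

    def prepared_templates(self) -> list[TemplateMap]:
        return [prepare_template(t) for t in self.template_maps()]

    def analysis_mask(self) -> AnalysisMask:
        t = self.truth
        grey = as_image(t.grey.astype(np.int16), t.affine)
        brain = as_image(t.brain.astype(np.int16), t.affine)
        coverage = [brain]
        return build_analysis_mask(self.prepared_templates(), grey, coverage, brain=brain)

    # -- BOLD ------------------------------------------------------------
    def events(self, subject: int, session: str, run: int) -> pd.DataFrame:
        cfg = self.config
        rng = _rng(cfg, subject, SESSIONS.index(session), run, 3)
        return make_event_schedule(cfg, rng)

    def latent_series(self, subject: int, session: str, run: int) -> np.ndarray:
        """The run's true latent target series (T x K), exactly standardized."""
        cfg = self.config
        rng = _rng(cfg, subject, SESSIONS.index(session), run, 0)
        s = _ar1_series(rng, cfg.scans_per_run, cfg.n_targets, cfg.ar_coef)
        return s

    def session_runs(self, subject: int, session: str):
        """Generate the runs of one subject-session: (bold images, event tables)."""
        return simulate_subject_session(self.truth, subject, session)

    def pet(self, subject: int):
        return simulate_pet(self.truth, subject)

    def write(self, out_dir, overwrite: bool = False) -> None:
        write_cohort(self, out_dir, overwrite=overwrite)


def make_templates(config: SynthConfig, return_truth_arrays: bool = False):
    """Synthetic molecular density templates as Gaussian blob mixtures.

    Each target owns two private blobs; a shared central blob weighted by
    the overlap parameter rho controls the pairwise spatial correlation
    (rho = 0: near-orthogonal supports; rho = 0.9: the DAT/SERT regime with
    r > 0.8). Each template reserves a disjoint reference block (excluded
    from stage 1, re-included in stage 2).
    """
    shape = config.shape
    K = config.n_targets
    brain = _ellipsoid(shape)
    grey = ndimage.binary_erosion(brain, iterations=1)

    own_centers = [
        [_frac_center(shape, 0.30, 0.28, 0.55), _frac_center(shape, 0.68, 0.35, 0.40)],
        [_frac_center(shape, 0.30, 0.72, 0.55), _frac_center(shape, 0.68, 0.65, 0.40)],
        [_frac_center(shape, 0.50, 0.20, 0.40), _frac_center(shape, 0.22, 0.50, 0.45)],
        [_frac_center(shape, 0.50, 0.80, 0.40), _frac_center(shape, 0.78, 0.50, 0.45)],
    ]
    shared_center = _frac_center(shape, 0.50, 0.50, 0.55)
    sigma = config.blob_sigma_vox or max(min(shape) / 7.0, 1.2)

    shared = _blob(shape, shared_center, sigma)
    templates_raw = np.zeros((K,) + tuple(shape))
    reference_masks = np.zeros((K,) + tuple(shape), dtype=bool)
    for k in range(K):
        own = sum(_blob(shape, c, sigma) for c in own_centers[k % len(own_centers)])
        raw = (1.0 - config.rho) * own + config.rho * shared + 0.02
        raw[~brain] = 0.0
        templates_raw[k] = raw
        # disjoint reference block per target along the low-x brain edge
        x0 = 1 + k * 3
        z0 = shape[2] // 2 - 1
        ref = np.zeros(shape, dtype=bool)
        ref[x0 : x0 + 2, shape[1] // 2 - 1 : shape[1] // 2 + 1, z0 : z0 + 2] = True
        reference_masks[k] = ref & brain
        if not reference_masks[k].any():
            raise ValueError("grid too small to place a reference block inside the brain")

    names = [f"target{k}" for k in range(K)]
    affine = config.affine
    maps = [
        TemplateMap(
            name=names[k],
            img=as_image(templates_raw[k], affine),
            domain=brain.copy(),
            reference_mask=reference_masks[k],
        )
        for k in range(K)
    ]
    grey_img = as_image(grey.astype(np.int16), affine)
    if return_truth_arrays:
        return maps, grey_img, (templates_raw, reference_masks, grey, brain)
    return maps, grey_img


def make_event_schedule(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Randomized zero-duration outcome events with a minimum spacing.

    All four conditions appear ``events_per_condition_per_run`` times; onsets
    are drawn by distributing the slack time between consecutive events.
    """
    n_per = config.events_per_condition_per_run
    n_events = n_per * len(CONDITIONS)
    duration = config.scans_per_run * config.tr_s
    lead_in, tail = 6.0, 25.0  # leave room for the HRF to evolve
    usable = duration - lead_in - tail
    slack = usable - (n_events - 1) * config.min_event_spacing_s
    if slack <= 0:
        raise ValueError(
            f"cannot place {n_events} events with spacing {config.min_event_spacing_s}s "
            f"in a {duration:.0f}s run"
        )
    gaps = rng.dirichlet(np.ones(n_events)) * slack
    onsets = lead_in + np.cumsum(gaps) + np.arange(n_events) * config.min_event_spacing_s
    labels = np.repeat(list(CONDITIONS), n_per)
    rng.shuffle(labels)
    return pd.DataFrame(
        {"onset": onsets, "duration": 0.0, "trial_type": labels}
    )


def _ar1_series(rng: np.random.Generator, n: int, k: int, phi: float) -> np.ndarray:
    """k AR(1) series of length n, exactly standardized (mean 0, sd 1, ddof=1)."""
    eps = rng.standard_normal((n, k))
    s = signal.lfilter([1.0], [1.0, -phi], eps, axis=0)
    s = s - s.mean(axis=0)
    s = s / s.std(axis=0, ddof=1)
    return s


def _orthogonalize(maps: np.ndarray, basis: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Project spatial maps (leading axis) off [1, basis] over the mask voxels."""
    B = np.column_stack([np.ones(int(mask.sum()))] + [b[mask] for b in basis])
    Q, _ = np.linalg.qr(B)
    out = maps.copy()
    for i in range(out.shape[0]):
        v = out[i][mask]
        out[i][mask] = v - Q @ (Q.T @ v)
        out[i][~mask] = 0.0
    return out


def build_cohort_truth(config: SynthConfig) -> CohortTruth:
    """Draw the cohort-level ground truth (templates, maps, ki, RPE effects)."""
    maps, _, (templates_raw, reference_masks, grey, brain) = make_templates(
        config, return_truth_arrays=True
    )
    shape = tuple(config.shape)
    K = config.n_targets

    # Analysis-ready template values: reference-masked, min-max rescaled.
    # The base coupling map of target k is its (rescaled) density map demeaned
    # over the stage-1 voxels and extended over the brain (reference voxels
    # carry their own density-derived coupling: connectivity exists there even
    # though stage 1 never sees them).
    prepared = [prepare_template(m) for m in maps]
    grey_img = as_image(grey.astype(np.int16), config.affine)
    brain_img = as_image(brain.astype(np.int16), config.affine)
    amask = build_analysis_mask(prepared, grey_img, [brain_img], brain=brain_img)
    stage1 = amask.stage1

    coupling = np.zeros((K,) + shape)
    for k in range(K):
        dom = prepared[k].domain
        raw = templates_raw[k]
        lo, hi = raw[dom].min(), raw[dom].max()
        rescaled_full = np.where(brain, (raw - lo) / (hi - lo), 0.0)
        m = rescaled_full[stage1].mean()
        coupling[k] = np.where(brain, rescaled_full - m, 0.0) * config.coupling_amplitude

    x_demeaned = [
        np.where(stage1, prepared[k].values - prepared[k].values[stage1].mean(), 0.0)
        for k in range(K)
    ]

    # Drug-shift blobs (disjoint from the reference blocks, inside stage 1),
    # orthogonalized against the templates so the two stages stay separable.
    sigma = max(min(shape) / 9.0, 1.0)
    delta_centers = [
        _frac_center(shape, 0.40, 0.40, 0.62),
        _frac_center(shape, 0.60, 0.60, 0.62),
        _frac_center(shape, 0.40, 0.60, 0.62),
        _frac_center(shape, 0.60, 0.40, 0.62),
    ]
    delta_raw = np.zeros((K,) + shape)
    effect_mask = np.zeros((K,) + shape, dtype=bool)
    for k in range(K):
        blob = _blob(shape, delta_centers[k % len(delta_centers)], sigma)
        blob = np.where(stage1, blob, 0.0)
        delta_raw[k] = blob * config.delta_scale * config.coupling_amplitude
        effect_mask[k] = blob > 0.5 * blob.max()
    delta = _orthogonalize(delta_raw, np.stack(x_demeaned), stage1)

    task_centers = [
        _frac_center(shape, 0.35, 0.50, 0.35),
        _frac_center(shape, 0.65, 0.50, 0.35),
        _frac_center(shape, 0.50, 0.35, 0.65),
        _frac_center(shape, 0.50, 0.65, 0.65),
    ]
    task_raw = np.stack(
        [
            np.where(stage1, _blob(shape, c, sigma), 0.0) * config.task_amplitude
            for c in task_centers
        ]
    )
    task_maps = _orthogonalize(task_raw, np.stack(x_demeaned), stage1)

    interaction_support = _orthogonalize(
        np.where(stage1, delta_raw != 0, 0.0) * delta_raw / max(config.delta_scale, 1e-12),
        np.stack(x_demeaned),
        stage1,
    )
    interaction_gain = np.zeros((K, len(CONDITIONS)))
    interaction_gain[0, CONDITIONS.index("unexpected_reward")] = config.interaction_gain
    gamma = np.zeros(K)
    gamma[0] = config.gamma  # only the dopamine-transporter analogue is moderated

    rng = _rng(config, 100)
    ki = rng.normal(config.ki_mean, config.ki_sd, size=config.n_subjects)
    ki = np.abs(ki)  # truncate positive (reflect: negligible mass at this scale)
    rpe_noise_sd = config.rpe_noise_frac * config.rpe_lambda * config.ki_sd
    rpe = config.rpe_lambda * (ki - ki.mean()) + rng.normal(
        0.0, rpe_noise_sd, size=config.n_subjects
    )

    # PET geometry: a striatal-like ROI around the shared blob center and a
    # cerebellar-like reference block in the bottom slab, away from the ROI.
    roi_center = _frac_center(shape, 0.50, 0.50, 0.55)
    roi = _blob(shape, roi_center, sigma) > 0.6
    roi &= brain
    z0 = shape[2] // 2 - 1
    pet_ref = np.zeros(shape, dtype=bool)
    pet_ref[
        shape[0] - 3 : shape[0] - 1, shape[1] // 2 - 1 : shape[1] // 2 + 1, z0 : z0 + 2
    ] = True
    pet_ref &= brain & ~roi
    if not pet_ref.any():
        raise ValueError("grid too small to place the PET reference block inside the brain")
    base_ki = 0.005 + 0.015 * _blob(shape, roi_center, 2.5 * sigma)

    return CohortTruth(
        config=config,
        affine=config.affine,
        target_names=[m.name for m in maps],
        templates_raw=templates_raw,
        reference_masks=reference_masks,
        grey=grey,
        brain=brain,
        coupling=coupling,
        delta=delta,
        effect_mask=effect_mask,
        task_maps=task_maps,
        interaction_support=interaction_support,
        interaction_gain=interaction_gain,
        gamma=gamma,
        ki=ki,
        rpe_effect=rpe,
        pet_roi=roi,
        pet_reference=pet_ref,
        pet_ki_map=base_ki,
        subject_ids=[f"sub-{i + 1:02d}" for i in range(config.n_subjects)],
    )


def session_coupling(truth: CohortTruth, subject: int, session: str) -> np.ndarray:
    """The K coupling maps in effect for one subject-session."""
    cfg = truth.config
    coupling = truth.coupling.copy()
    if session == "drug":
        d = truth.ki[subject] - truth.ki_sample_mean
        for k in range(cfg.n_targets):
            coupling[k] = coupling[k] + truth.delta[k] * (1.0 + truth.gamma[k] * d)
    return coupling


def simulate_subject_session(truth: CohortTruth, subject: int, session: str):
    """Generate the 4D BOLD runs and event tables of one subject-session."""
    if session not in SESSIONS:
        raise ValueError(f"session must be one of {SESSIONS}")
    cfg = truth.config
    shape = tuple(cfg.shape)
    coupling = session_coupling(truth, subject, session)
    sess_idx = SESSIONS.index(session)
    stage2_proxy = truth.brain  # noise/signal bookkeeping over in-brain voxels

    runs, events_list = [], []
    for run in range(cfg.runs_per_session):
        rng_latent = _rng(cfg, subject, sess_idx, run, 0)
        rng_drift = _rng(cfg, subject, sess_idx, run, 1)
        rng_noise = _rng(cfg, subject, sess_idx, run, 2)
        rng_events = _rng(cfg, subject, sess_idx, run, 3)

        T = cfg.scans_per_run
        s = _ar1_series(rng_latent, T, cfg.n_targets, cfg.ar_coef)
        events = make_event_schedule(cfg, rng_events)
        regs = condition_regressors(events, cfg.tr_s, T, HrfParams()).to_numpy()

        sig = np.zeros(shape + (T,))
        for k in range(cfg.n_targets):
            sig += coupling[k][..., None] * s[:, k]
        for c in range(len(CONDITIONS)):
            sig += truth.task_maps[c][..., None] * regs[:, c]
        for k in range(cfg.n_targets):
            for c in range(len(CONDITIONS)):
                g = truth.interaction_gain[k, c]
                if g != 0.0:
                    sig += g * truth.interaction_support[k][..., None] * (
                        s[:, k] * regs[:, c]
                    )

        data = sig + 100.0
        basis = dct_drift_basis(T, cfg.tr_s, cfg.drift_cutoff_s)
        drift = basis @ rng_drift.normal(0.0, cfg.drift_amplitude, size=basis.shape[1])
        data = data + drift  # spatially constant scanner drift

        if np.isfinite(cfg.snr):
            centered = sig - sig.mean(axis=-1, keepdims=True)
            sig_sd = float(np.sqrt((centered[stage2_proxy] ** 2).mean()))
            noise_sd = sig_sd / cfg.snr
            eps = rng_noise.standard_normal(shape + (T,))
            eps = signal.lfilter([1.0], [1.0, -cfg.ar_coef], eps, axis=-1)
            sigma_vox = cfg.noise_smooth_fwhm_mm * FWHM_TO_SIGMA / cfg.voxel_size_mm
            eps = ndimage.gaussian_filter(
                eps, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0), mode="constant"
            )
            eps *= noise_sd / eps[stage2_proxy].std()
            data = data + eps

        runs.append(as_image(data, truth.affine, tr=cfg.tr_s))
        events_list.append(events)
    return runs, events_list


def simulate_pet(truth: CohortTruth, subject: int):
    """Dynamic PET frames for one subject, Patlak-conjugate by construction.

    The reference TAC is a gamma-variate input curve; every tissue voxel
    follows C(t) = ki(v) * int C_ref + V * C_ref with the subject's true ki
    inside the striatal ROI, plus optional Gaussian frame noise.

    Returns (pet image, reference-mask image, roi image, schedule).
    """
    cfg = truth.config
    schedule = cfg.schedule
    t = schedule.mid_min
    # gamma-variate bolus peaking ~15 min plus a slow recirculation plateau,
    # so reference activity stays well above zero across the 89-min scan
    cref = (t / 10.0) ** 1.5 * np.exp(-t / 10.0) + 0.3 * (1.0 - np.exp(-t / 10.0))
    cref = cref / cref.max()
    cum = cumulative_integral(cref, schedule)

    ki_map = truth.pet_ki_map.copy()
    ki_map[truth.pet_roi] = truth.ki[subject]
    shape = tuple(cfg.shape)
    data = np.zeros(shape + (len(schedule),))
    brain = truth.brain
    data[brain] = (
        ki_map[brain][:, None] * cum[None, :]
        + cfg.pet_blood_volume * cref[None, :]
    )
    data[truth.pet_reference] = cref  # pure reference tissue

    if cfg.pet_noise_frac > 0:
        rng = _rng(cfg, subject, 200)
        peak = float(data[truth.pet_roi].max())
        data[brain] += rng.normal(0.0, cfg.pet_noise_frac * peak, size=data[brain].shape)

    pet = as_image(data, truth.affine, tr=1.0)
    ref_img = as_image(truth.pet_reference.astype(np.int16), truth.affine)
    roi_img = as_image(truth.pet_roi.astype(np.int16), truth.affine)
    return pet, ref_img, roi_img, schedule


def simulate_cohort(config: SynthConfig) -> Cohort:
    """Build a cohort (lazy volumes, full ground truth) from a config."""
    return Cohort(build_cohort_truth(config))


# ---------------------------------------------------------------------------
# Direct group-level simulators (contrast-map scale), used to study the
# calibration and power of the permutation inference without regenerating
# full BOLD cohorts.
# ---------------------------------------------------------------------------

def simulate_group_contrasts(
    n_subjects: int,
    mask: np.ndarray,
    rng: np.random.Generator,
    delta_map: np.ndarray | None = None,
    ki: np.ndarray | None = None,
    gamma: float = 0.0,
    noise_sd: float = 0.023,
    smooth_sigma_vox: float = 0.9,
) -> np.ndarray:
    """Per-subject drug-placebo contrast maps at the group-model scale.

    contrast_j = delta_map * (1 + gamma*(ki_j - mean ki)) + smooth noise.
    The default noise amplitude and smoothness match the first-level
    contrast estimation error the full generator produces at SNR 1 (see the
    methods note). With ``delta_map=None`` this yields null cohorts for
    calibration studies.
    """
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    out = np.zeros((n_subjects,) + shape)
    d = np.zeros(n_subjects) if ki is None else ki - np.mean(ki)
    for j in range(n_subjects):
        eps = rng.standard_normal(shape)
        eps = ndimage.gaussian_filter(eps, sigma=smooth_sigma_vox, mode="constant")
        eps *= noise_sd / eps[mask].std()
        m = eps
        if delta_map is not None:
            m = m + delta_map * (1.0 + gamma * d[j])
        out[j] = np.where(mask, m, 0.0)
    return out


# ---------------------------------------------------------------------------
# On-disk BIDS-like serialization
# ---------------------------------------------------------------------------

def _truth_to_json(truth: CohortTruth) -> dict:
    cfg = asdict(truth.config)
    cfg["shape"] = list(cfg["shape"])
    cfg["frame_blocks"] = [list(b) for b in cfg["frame_blocks"]]
    return {
        "config": cfg,
        "subject_ids": truth.subject_ids,
        "target_names": truth.target_names,
        "ki": truth.ki.tolist(),
        "rpe_effect": truth.rpe_effect.tolist(),
        "gamma": truth.gamma.tolist(),
        "interaction_gain": truth.interaction_gain.tolist(),
        "ki_sample_mean": truth.ki_sample_mean,
    }


def write_cohort(cohort: Cohort, out_dir, overwrite: bool = False) -> None:
    """Materialize a cohort as NIfTI + TSV under a BIDS-like tree."""
    truth = cohort.truth
    cfg = cohort.config
    out_dir = os.fspath(out_dir)
    truth_file = os.path.join(out_dir, "truth.json")
    if os.path.exists(truth_file) and not overwrite:
        raise FileExistsError(f"{out_dir} already holds a cohort; pass overwrite=True")
    os.makedirs(out_dir, exist_ok=True)

    study = os.path.join(out_dir, "study")
    os.makedirs(study, exist_ok=True)
    for k, tmap in enumerate(cohort.template_maps()):
        write_volume(tmap.img, os.path.join(study, f"template-{tmap.name}.nii.gz"))
        write_volume(
            as_image(truth.reference_masks[k].astype(np.int16), truth.affine),
            os.path.join(study, f"template-{tmap.name}_refmask.nii.gz"),
        )
    write_volume(
        as_image(truth.grey.astype(np.int16), truth.affine),
        os.path.join(study, "grey.nii.gz"),
    )
    write_volume(
        as_image(truth.brain.astype(np.int16), truth.affine),
        os.path.join(study, "brain.nii.gz"),
    )

    truth_dir = os.path.join(out_dir, "truth_maps")
    os.makedirs(truth_dir, exist_ok=True)
    for k, name in enumerate(truth.target_names):
        for label, arr in (
            ("coupling", truth.coupling[k]),
            ("delta", truth.delta[k]),
            ("effectmask", truth.effect_mask[k].astype(np.int16)),
        ):
            write_volume(
                as_image(arr, truth.affine),
                os.path.join(truth_dir, f"{name}_{label}.nii.gz"),
            )

    for j, sub in enumerate(truth.subject_ids):
        for session in SESSIONS:
            func = os.path.join(out_dir, sub, f"ses-{session}", "func")
            os.makedirs(func, exist_ok=True)
            runs, events = cohort.session_runs(j, session)
            for r, (img, ev) in enumerate(zip(runs, events)):
                stem = f"{sub}_ses-{session}_task-reversal_run-{r + 1}"
                write_volume(img, os.path.join(func, f"{stem}_bold.nii.gz"))
                write_events(ev, os.path.join(func, f"{stem}_events.tsv"))
        pet_dir = os.path.join(out_dir, sub, "pet")
        os.makedirs(pet_dir, exist_ok=True)
        pet, ref_img, roi_img, schedule = cohort.pet(j)
        write_volume(pet, os.path.join(pet_dir, f"{sub}_pet.nii.gz"))
        write_volume(ref_img, os.path.join(pet_dir, f"{sub}_refmask.nii.gz"))
        write_volume(roi_img, os.path.join(pet_dir, f"{sub}_roi.nii.gz"))
        schedule.write_tsv(os.path.join(pet_dir, "frames.tsv"))

    pd.DataFrame({"subject_id": truth.subject_ids, "ki_cer": truth.ki}).to_csv(
        os.path.join(out_dir, "covariates.tsv"), sep="\t", index=False
    )
    with open(truth_file, "w") as fh:
        json.dump(_truth_to_json(truth), fh, indent=2, sort_keys=True)


def truth_checksum(truth: CohortTruth) -> str:
    """Stable digest of the serialized scalar truth (determinism checks)."""
    payload = json.dumps(_truth_to_json(truth), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
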