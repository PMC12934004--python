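# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limits of what the test suite establishes.

## Dual regression

The stage-1 spatial regression demeans both the data volume and the
template columns across the in-mask voxels and solves the normal equations
without an explicit intercept — algebraically identical to including one.
All supplied templates are solved jointly; the single-target mode of the
pipeline simply runs the extraction (and the subsequent GLM) once per
template. The solve is refused when the demeaned template Gram matrix has a
condition number above 1e8, with the pairwise spatial correlations printed
in the error: a rank-deficient spatial design has no meaningful per-target
series.

Templates are prepared by removing the reference-region voxels used in
their construction from the valid domain *first*, then min–max rescaling
over the remaining voxels, so an extreme value inside the reference region
cannot distort the scale. The stage-1 mask is the intersection of the
template domains, a grey-matter mask and all sessions' coverage; the
stage-2 mask is all covered in-brain voxels, re-including the reference
regions. Grid equality is enforced at 1e-4 mm on the affine; anything
looser requires an explicit resample (trilinear or nearest via nilearn).

The stage-2 GLM per run contains: the four HRF-convolved outcome
regressors, the per-run standardized (mean 0, sample sd 1) target series,
their elementwise products with the outcome regressors (interactions formed
at the BOLD level, not deconvolution-based PPI), a discrete-cosine drift
basis with floor(2·T·TR/cutoff)+1 terms (default cutoff 128 s), and a run
intercept. Task/target/interaction columns are stacked across the runs of a
session; drift and intercept columns are per-run blocks. Estimation is OLS;
an optional single-coefficient AR(1) prewhitening (estimated from pooled
residuals, applied per run) is available behind `whitening="ar1"`. OLS is
the default because group inference uses only contrast maps, which are
unbiased under OLS. Normalization of the target series is per run (the
runs are separate acquisitions).

The canonical HRF is the double-gamma difference
g(t; 6, 1) − g(t; 16, 1)/6 (peak ≈ 5 s, undershoot ≈ 15 s), configurable
through `HrfParams`; zero-duration outcome events are impulses, events with
positive duration are integrated boxcars, both on a TR/20 grid. The
implementation is cross-checked in the tests against nilearn's canonical
SPM regressor.

All-zero design columns (a condition without events) are permitted — the
pseudo-inverse assigns them beta 0 — while genuine collinearity between
non-degenerate columns aborts with the most correlated column pair named.
Variance inflation factors are reported for every column
(VIF_j = 1/(1−R²_j)); the pipeline warns when any target/interaction VIF,
*or* any spatial (template) VIF, exceeds 5. The spatial VIF is the
operative diagnostic for overlapping templates: two density maps with
spatial correlation r ≈ 0.97 give a spatial VIF ≈ 18 even when the
extracted time series happen to be nearly orthogonal.

## Patlak quantification

The reference-region Patlak estimator regresses y(t) = C_T/C_ref on
x(t) = ∫₀ᵗC_ref/C_ref over the frames with start ≥ t* and end ≤ t_end
(default 24–89 min; a frame straddling the boundary is excluded — a
conservative reading of the window). The running integral is trapezoidal
over frame mid-times with the TAC linearly extrapolated to t = 0 (clipped
at zero), which makes the rule exact for constant and for linear reference
curves; for a smooth gamma-variate input it agrees with fine-grid
quadrature to well under 2% at all frames past 5 min. The fit is unweighted
OLS by default (all frames in the default window share one duration);
frame-duration weighting is available. Negative frame activities are
tolerated in the tissue TAC, but non-positive reference activity inside the
window is an error, since the Patlak ratio is undefined there. Decay
correction is assumed to have been applied upstream.

Voxelwise maps exploit that the Patlak abscissa is shared by all voxels, so
the map is a single closed-form regression; optional Gaussian smoothing
(8 mm FWHM is the conventional group-analysis choice) is applied to the
finished map. The subject-level scalar is the unsmoothed ROI mean by
default.

## Group inference

Contrasts are voxelwise drug − placebo differences per subject and target.
The one-sample model uses t = mean/(sd/√n) on n−1 df; the covariate model
regresses the contrast on mean-centered k_i (n−2 df). Cluster-forming
threshold: one-sided p < 0.001 per direction; connectivity 26 by default
(6 and 18 available). Cluster-level FWE p-values come from the permutation
null of the **maximum cluster extent pooled over both directions**
(sign-flipping for the one-sample model, Freedman–Lane residual permutation
for the covariate model), with the add-one rule
p = (1 + #{max_k* ≥ k})/(1 + n_perm). Pooling the directions makes
"any cluster with p_fwe < α in either direction" a max-statistic test whose
family-wise error is exactly α — the property the calibration study
verifies. A consequence worth knowing: the null maxima are symmetric under
flipping all signs, so with exhaustive sign-flip enumeration (used
automatically whenever 2ⁿ ≤ n_perm, which also makes the p-values exact and
independent of subject ordering) the smallest attainable p is 2/2ⁿ.

Saturated statistics (zero residual variance) are carried as a large finite
sentinel plus a flag, never as a non-finite number; cluster tables render
the corresponding Z as "Inf". The t→Z conversion is probability-matched in
log space (`ndtri_exp` of the t log-survival), so extreme finite t values
convert without underflow. Fewer than six subjects triggers a warning (the
permutation null is then very coarse) but still returns a result. Multiple
targets are treated as separate families, with no cross-target correction.

## Synthetic cohort: what it emulates

`SynthConfig` defaults define the study conditions: 16 subjects, two
sessions (placebo, drug), 3 runs × 120 scans at TR 2.32 s, a 20×20×12 grid
at 2 mm, the standard 24-frame PET schedule (4×1, 3×2, 3×3, 14×5 min), and
k_i ~ N(0.010, 0.002) min⁻¹ truncated positive — a plausible scale for
[¹⁸F]FDOPA influx rates; no population values for this quantity are being
reproduced, only the scale.

Templates are mixtures of Gaussian blobs inside an ellipsoidal brain; an
overlap parameter ρ mixes in a shared central blob, so ρ = 0 gives
near-orthogonal maps and ρ = 0.9 the collinear regime in which two targets
cannot be separated. Each template reserves a disjoint reference block
(excluded from stage 1, re-included in stage 2).

Per run the BOLD signal is

    y(v,t) = Σ_k c_k(v)·s_k(t) + Σ_c A_c(v)·r_c(t)
           + Σ_{k,c} g_{kc}·m_k(v)·s_k(t)·r_c(t) + drift + 100 + noise,

with unit-variance AR(1) (φ = 0.3) latent series s_k standardized exactly
per run, HRF-convolved outcome regressors r_c from randomized event
schedules (all four outcome conditions, zero duration, minimum spacing
8 s), and AR(1) Gaussian noise smoothed spatially (4 mm FWHM) and scaled so
that SNR = rms(signal)/sd(noise) (default 1). In the drug session the
coupling of target k becomes c_k + Δ_k·(1 + γ_k·(k_i − mean k_i)); by
default only the first target (the dopamine-transporter analogue) is
moderated (γ = 100 per min⁻¹, i.e. ±2 sd of k_i swings the drug effect by
±40%), mirroring a design in which the dopamine network, but not the
noradrenaline network, scales with synthesis capacity. The drug-shift peak
is 50% of the coupling amplitude — a strong but plausible pharmacological
modulation chosen so a 16-subject cohort has realistic power.

Three constructions make the generator *exactly* conjugate to the analysis
at zero noise, which is what turns the tests into sharp algebraic checks:
task-activation, drug-shift and interaction-support maps are orthogonalized
against [1, templates] over the stage-1 voxels (so they cannot leak into
the extracted series); scanner drift is drawn inside the analysis DCT span;
and the PET tissue curves are built with the same running-integral rule the
Patlak fit uses. The per-subject "RPE drug effect" is emulated as
λ·(k_i − mean k_i) plus noise (sd 0.7·λ·sd(k_i)), closing the loop for the
regional-correlation analysis.

A second, cheaper simulator (`simulate_group_contrasts`) generates
drug−placebo contrast maps directly at the group-model scale; its default
noise amplitude (sd 0.023) and smoothness (σ ≈ 0.9 voxels) were set to
match the first-level contrast estimation error the full generator produces
at SNR 1, measured once during development. It drives the calibration and
covariate-moderation studies, where hundreds of cohorts are needed.

What the generator does **not** emulate: realistic anatomy, motion and
scanner artifacts, biophysical BOLD nonlinearity, physiological noise
spectra, inter-regional signal leakage between templates, or the empirical
distribution of real [¹⁸F]FDOPA curves. Passing tests therefore demonstrate
internal consistency, statistical calibration, and correct algebra of the
estimators — not performance on real data.

## Validation study sizes

The studies in `reactfc.validation` (run by `scripts/acceptance.py` and the
end-to-end tests) use: a 60-voxel/12-scan fixture for the oracle checks;
the full 16-subject default cohort for zero-noise inversion; 10 subjects
for latent recovery; 20 effect and 20 matched null full-pipeline cohorts
(500 permutations each) for detection; 200 null cohorts × 500 permutations
for calibration (the test suite uses 120 × 300 with the band recomputed for
that count); 50 cohorts for covariate moderation; 500 Monte-Carlo
replicates for Patlak noise bias. These sizes give stable rates while
keeping a full validation run in the minutes range on one CPU.

## Known limitations

- Permutation inference replaces the random-field-theory cluster FWE of
  SPM-based analyses; p-values from the two approaches are not expected to
  agree numerically.
- The AR(1) prewhitening option estimates a single global coefficient, not
  SPM's spatially regularized autoregressive model.
- The Patlak implementation is the graphical method only; no compartmental
  (K1, k2, k3) fitting.
- Reference-mask geometry, exact first-level drift/whitening settings and
  the per-run vs per-session normalization of target series are
  under-determined in the literature this follows; the defaults above are
  the package's own documented choices, all configurable.
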