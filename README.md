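# reactfc

Molecular target-enriched fMRI connectivity analysis: dual-regression
extraction of transporter-enriched networks from task fMRI, reference-region
Patlak quantification of dopamine synthesis capacity from dynamic PET, and
covariate-moderated group inference with permutation cluster-level FWE
correction — together with a ground-truth synthetic cohort generator that
makes every stage testable end to end.

## Who this is for

Pharmaco-fMRI studies often ask whether a drug's effect on brain activity
runs through a specific neurotransmitter system. `reactfc` implements the
REACT approach (Receptor-Enriched Analysis of Connectivity by Targets):
population-average density maps of molecular targets — e.g. the dopamine
(DAT), noradrenaline (NET) and serotonin (SERT) transporters — are used as
spatial regressors to extract, per subject and session, the BOLD signal
component associated with each target system, whose drug modulation can
then be tested at the group level and related to an independent PET measure
of dopamine synthesis capacity (the [¹⁸F]FDOPA influx rate
k<sub>i</sub><sup>cer</sup>).

## The model

**Stage 1 (spatial regression).** For each fMRI volume `y_t` restricted to
the stage-1 analysis mask (template domains ∩ grey matter ∩ scanner
coverage), solve the OLS problem

    ỹ_t = X̃ s(t) + ε,

where the columns of `X̃` are the reference-masked, min–max rescaled,
spatially demeaned molecular templates and `ỹ_t` the demeaned volume.
`s_k(t)` is the target-k–enriched time series ("the template applied as a
spatial filter").

**Stage 2 (temporal regression).** Per run the normalized `s_k` enter a
voxelwise GLM over all covered in-brain voxels (reference regions
re-included), alongside four HRF-convolved task-outcome regressors
(expected/unexpected reward/punishment), their interactions with `s_k`, a
discrete-cosine drift basis (128 s cutoff) and run intercepts. The beta map
of `s_k` is the subject's target-enriched functional connectivity map.

**PET quantification.** With reference region activity `C_ref` (cerebellar
grey matter) and tissue activity `C_T`, the Gjedde–Patlak plot

    C_T(t)/C_ref(t) = k_i · (∫₀ᵗ C_ref dτ)/C_ref(t) + V

is linear after equilibrium; `k_i` (min⁻¹) is fit by OLS over the frames
fully inside the 24–89 min window (exactly the 13 late five-minute frames
of the standard 24-frame schedule), and the subject's dopamine synthesis
capacity is the mean over a ventral-striatum ROI.

**Group inference.** Per-subject drug−placebo contrasts are analyzed with a
one-sample t-test and with mean-centered k_i as covariate; voxels at
p < 0.001 (one-sided, each direction) form clusters whose extents receive
family-wise-error-corrected p-values from the permutation null of the
maximum cluster size (sign-flipping / Freedman–Lane).

## Worked example

```python
import numpy as np
from reactfc import SynthConfig, AnalysisOptions, simulate_cohort, run_pipeline

cohort = simulate_cohort(SynthConfig(seed=2))          # n=16, two sessions
result = run_pipeline(cohort, AnalysisOptions(n_perm=500, seed=3))

tab = result.cluster_tables["target0"]["covariate"]
print(tab[["direction", "extent_k", "peak_t", "p_fwe"]].head(1))
print("correlation with emulated RPE effect:",
      round(result.correlation["r"], 3), round(result.correlation["p"], 6))
print("max ki error:",
      float(np.max(np.abs(result.ki_table["ki_cer"] - cohort.truth.ki))))
```

prints (seed 2/3):

```
  direction  extent_k     peak_t     p_fwe
0       pos        51  17.138413  0.001996
correlation with emulated RPE effect: 0.831 6.5e-05
max ki error: 0.0006922363961635487
```

meaning: the ki-moderated drug effect on the first target's connectivity is
detected as a 51-voxel cluster surviving cluster-level FWE (p ≈ 0.002); the
cluster-mean drug effect correlates r ≈ 0.83 with the independently
emulated reward-prediction-error drug effect (both are driven by the same
per-subject dopamine synthesis capacity); and the PET stage recovers each
subject's true k_i within ~7×10⁻⁴ min⁻¹ at the default frame noise.

The same analysis is scriptable from a shell:

```bash
reactfc simulate -c run.yaml -o dataset/
reactfc pipeline -c run.yaml -d dataset/ -o results/
```

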