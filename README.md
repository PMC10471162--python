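# lcgrad

Connectopic gradient mapping of the locus coeruleus (LC): voxel-wise
functional-connectivity gradients within a small bilateral brainstem ROI,
third-order trend-surface summaries of their spatial layout, and the cohort
statistics that link those summaries to age, behavior, gradient
clusterability, and clinical screening groups.

## The problem

The LC is a tiny noradrenergic nucleus whose rostral and caudal parts
project to different targets (associative cortex and limbic areas vs
sensorimotor regions) and degenerate differently in aging and disease. In
resting-state fMRI this internal organization appears as a spatially
continuous *gradient*: each ROI voxel has a connectivity fingerprint (its
correlations with a set of cortical and subcortical parcels), fingerprints
of neighbouring voxels are similar, and the dominant axis of change runs
rostro-caudally. `lcgrad` is for researchers who want to estimate such
gradients inside a small ROI, describe them compactly, and run group-level
inference — plus a fully synthetic phantom with planted ground truth, so
every stage is testable without access to any imaging dataset.

## The method in brief

1. **Fingerprints** `F[v, p]` — Pearson correlation between voxel `v`'s
   series and parcel `p`'s mean series (after optional nuisance regression
   and 3 mm FWHM Gaussian smoothing *restricted to the mask*, with kernel
   renormalization at the boundary so no signal leaks in or out).
2. **Similarity** — eta-squared between fingerprints:
   `η² = 1 − Σ[(aᵢ−mᵢ)² + (bᵢ−mᵢ)²] / Σ[(aᵢ−M)² + (bᵢ−M)²]`.
3. **Graph** — keep edges above the largest threshold that leaves the graph
   connected (per hemisphere).
4. **Eigenmap** — the generalized eigenvector `(D − W)v = λDv` with the
   smallest nonzero eigenvalue; oriented so rostral (anterior) is high and
   min–max scaled to [0, 1].
5. **Trend surface** — per hemisphere, Bayesian ridge regression of the
   gradient on `x, y, z, x², y², z², x³, y³, z³` (z-scored mm coordinates;
   9 coefficients per hemisphere) with evidence-maximized hyperparameters.
6. **Statistics** — per-year-of-age group gradients and a nested F-test for
   age; sliding-window (20 subjects, step 5) behavioral analysis with
   partial R² and partial Spearman correlations; Calinski–Harabasz
   clusterability vs age; bootstrap MANOVA (Pillai) + Mann–Whitney contrasts
   between screening-defined groups; BH-FDR throughout.

See `docs/methods.md` for assumptions, parameter defaults, calibration
caveats of the windowed and bootstrap designs, and what the phantom does and
does not emulate.

## Worked example

```python
import lcgrad
from lcgrad import phantom

cfg = phantom.PhantomConfig(noise_sd=0.1, seed=7)
mask, _ = phantom.make_phantom_roi(cfg)
atlas = phantom.make_phantom_atlas(cfg, mask)
vol, truth = phantom.simulate_subject(cfg, mask, atlas)

model = lcgrad.ConnectopicModel.from_volumes(vol, mask, atlas, fwhm_mm=3.0)
res = model.fit()
print(res.summary())
```

```
Connectopic gradient fit
============================================================
voxels: 96   parcels: 30   timepoints: 200
  left: graph threshold 0.9896   lambda1 0.00369   flipped: True
 right: graph threshold 0.9906   lambda1 0.00338   flipped: False
------------------------------------------------------------
  term       left      right      |L-R|
     x   -0.03383   -0.04035    0.00653
     y    0.68462    0.70041    0.01579
     z   -0.12966   -0.12818    0.00148
    x2   -0.01105   -0.00499    0.00606
    y2   -0.09222   -0.07857    0.01365
    z2   -0.01445   -0.00892    0.00552
    x3    0.00105    0.00335    0.00229
    y3   -0.14120   -0.14767    0.00647
    z3    0.02062    0.01943    0.00119
    R2     0.9687     0.9767    0.02442  (asymmetry index)
```

Reading the table: the dominant gradient runs almost purely along the
anterior–posterior axis (large `y` coefficient, with `y²`/`y³` curvature
from the logistic transition planted in this phantom), the two hemispheres
agree (small `|L−R|` column, asymmetry index 0.024), and the trend surface
explains ≈97% of the gradient's spatial variance. The per-hemisphere graph
threshold and leading eigenvalue are reported for auditability. Checking the
estimate against this phantom's planted field:

```python
from scipy.stats import spearmanr
rows = res.gradient.coords.hemi_rows("left")
spearmanr(res.gradient.values[rows], truth.planted_field[rows]).statistic
# 0.997
```

Cohort-level analyses take a simulated cohort instead of one subject:

```python
cohort = phantom.simulate_cohort(292, seed=1)          # planted age & score effects
res = lcgrad.stats.per_year_age_analysis(cohort)       # group gradient per year
res = lcgrad.stats.window_behavior_analysis(cohort, "em_recognition")
res = lcgrad.stats.clusterability_vs_age(cohort)
res = lcgrad.stats.bootstrap_group_comparison(cohort, seed=1)
```

There is also a CLI (`lcgrad simulate | gradient | tsm | age | behavior |
clusterability | groups | all`) that writes NIfTI/TSV/JSON artifacts with
the resolved config and seed next to them, e.g.

```bash
lcgrad all --seed 7 --out runs/demo
```

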