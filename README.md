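# roifuse

ROI-level multimodal neuroimaging fusion for two-group case–control
studies. `roifuse` is aimed at researchers who already have
region-of-interest summaries of functional MRI (BOLD time series),
structural MRI (grey/white-matter volumes) and diffusion imaging (FA, RD,
MD) for each subject — typically over the 90-region AAL parcellation — and
want to ask, region by region, *where* and *through which modality* two
groups differ, and *how well* the combined information discriminates them.

## The method

For each ROI a multi-index fusion vector concatenates the three modality
blocks:

* 89 Fisher-z functional connectivity coefficients
  z = atanh r with every other ROI,
* 2 structural features (GM, WM volume),
* 3 diffusion features (FA, RD = (λ₂+λ₃)/2, MD = (λ₁+λ₂+λ₃)/3),

for m = 94 features per ROI (or m = 10 with the fMRI block reduced to its
first five principal components). Group differences are screened per ROI
with Wilks' lambda from the MANOVA dispersion matrices,

λ = |W| / |T|,  T = W + B,  χ² = −(n − 1 − (G + m)/2)·ln λ,  df = m(G − 1),

smaller λ meaning stronger separation. Group discrimination uses a nested
10-fold SVM (8 folds train / 1 tunes the kernel and C / 1 tests, with
in-fold z-scoring and two-sample-t feature selection), repeated with
re-randomised folds and assessed by permutation testing. Agreement between
per-modality classifiers is quantified by the Jaccard coefficient on
correctly-classified subject sets and Cohen's kappa on predicted labels,
and each modality's contribution to the fusion model by the ratio of
Cox–Snell R² = 1 − exp(2(ℓ₀−ℓ₁)/n) values from logistic fits.

A fully seeded synthetic-cohort generator (group-dependent ROI correlation
structure, mean-shifted scalar modalities at chosen effect sizes) makes
every stage testable without access to clinical data. See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a 160-subject cohort (80 per group, 12 ROIs) in which group 2 has
a 0.8-SD grey-matter deficit at ROI 5 and a +0.3 connectivity shift on the
edge between ROIs 5 and 8 (1-based), then screen and classify:

```python
from roifuse import (SynthCohortConfig, Effect, generate_cohort,
                     cohort_features, zscore_normalize, screen_rois,
                     ClassifierConfig, nested_cv)

cfg = SynthCohortConfig(
    n_per_group=80, n_roi=12, n_timepoints=200, seed=0,
    effects=[Effect(roi=4, modality="gm", size=0.8),          # 0-based API
             Effect(roi=4, modality="fc", size=0.3, partner=7)],
)
cohort, truth = generate_cohort(cfg)
fs = zscore_normalize(cohort_features(cohort))

screen = screen_rois(fs, cohort.labels)
print(screen[screen["measure"] == "fusion"].nsmallest(3, "p")
      [["roi", "m", "lam", "chi2", "p"]])

X = fs.data.reshape(cohort.n_subjects, -1)
rep = nested_cv(X, cohort.labels,
                ClassifierConfig(kernels=("linear", "rbf"),
                                 C_grid=(0.1, 1.0, 10.0),
                                 n_repeats=5, seed=0))
print(f"accuracy {rep.accuracy_mean:.3f} ± {rep.accuracy_sd:.3f}  "
      f"AUC {rep.auc:.3f}")
```

Output:

```
 roi   m      lam       chi2            p
   4  16 0.136339 298.891817 4.326241e-54
   7  16 0.155403 279.259590 4.944627e-50
   6  16 0.843955  25.448419 6.230042e-02
accuracy 0.979 ± 0.008  AUC 0.999
```

The two ROIs with overwhelmingly the smallest fusion p are exactly the
injected ROI (index 4) and its connectivity partner (index 7) — a
correlation edit perturbs the FC features of both endpoints — while the
next-best ROI is a null one at p ≈ 0.06. The nested-CV SVM on the fusion
features separates the groups at 97.9% accuracy.

The same analysis is available from the shell: `roifuse simulate`,
`fuse`, `screen`, `classify`, `concord`, `contribute`, or `roifuse run
--config run.yaml` for the whole pipeline with a manifest that makes the
run bit-reproducible.

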