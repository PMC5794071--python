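# Methods

`roifuse` implements an ROI-level fusion analysis for two-group multimodal
neuroimaging studies (e.g. patients vs. controls). This note documents the
statistical model, the synthetic-cohort generator used for validation, the
numerical choices, and the known limitations.

## The fusion feature model

Each subject contributes three preprocessed modality summaries over a
90-region anatomical parcellation (AAL order; region names are bundled in
`roifuse/data/aal90.tsv`):

* **fMRI** — an ROI × time BOLD matrix. For ROI *i* the functional
  connectivity feature vector is the Pearson correlation of ROI *i*'s time
  series with each of the other 89 ROIs, Fisher-z transformed
  (z = atanh r) to improve normality. 89 features per ROI.
* **sMRI** — grey- and white-matter volume of the ROI. 2 features.
* **DTI** — FA, RD and MD of the ROI, where RD = (λ₂+λ₃)/2,
  MD = (λ₁+λ₂+λ₃)/3 and FA is the normalised eigenvalue dispersion
  √(3/2)·‖λ−λ̄‖/‖λ‖ of the tensor eigenvalues λ₁ ≥ λ₂ ≥ λ₃. The "ratio of
  axial to radial diffusivity" shorthand sometimes used for FA is treated
  as informal; the standard dispersion formula is implemented. 3 features.

Concatenated per ROI this gives the 94-feature multi-index vector
X = [x(1), …, x(94)]ᵀ (89 + 2 + 3), or a 10-feature variant when the fMRI
block is replaced by its first five principal components. Any of the seven
modality combinations can be assembled. Features are z-scored column-wise;
the normaliser (and the per-ROI PCA) follows scikit-learn fit/transform
semantics, so inside cross-validation both are fitted on training subjects
only. A `global_norm` switch fits them once on all subjects instead, for
comparison with studies that normalise globally before cross-validating;
this is leaky by construction and is off by default.

## Wilks-lambda screening

For each ROI the m-dimensional vectors of the G groups are compared through
the within-group (W), between-group (B) and total (T = W + B) dispersion
matrices (raw cross-product sums). The test statistic is Wilks' lambda

    λ = |W| / |T| ∈ (0, 1],

smaller λ meaning stronger separation, with significance from Bartlett's
large-sample transform

    χ² = −(n − 1 − (G + m)/2) · ln λ,   df = m(G − 1).

Determinants are computed via `slogdet` to avoid overflow at m = 94.
The Bartlett scale factor requires n > 1 + (G + m)/2 and |T| ≠ 0; ROIs
failing either condition are reported with an explicit reason rather than
dropped. An optional ridge path adds ε = 10⁻⁸·tr(T)/m to the diagonals of W
and T, rescuing nearly singular cases at the cost of slight bias; it is off
by default. Per-ROI "best measure" tallies break exact p ties by the fixed
precedence fusion > fMRI > sMRI > DTI (with a warning), so tallies are
reproducible.

Two univariate helpers cover cohort-matching tables: a pooled-variance
two-sample t-test that also accepts (mean, SD, n) summaries, and the 2×2
Pearson chi-square without continuity correction.

## Classification

The SVM harness uses a three-role 10-fold design: per rotation, eight folds
train, one fold picks the kernel (linear / polynomial degree 3 / RBF) and
C ∈ {10⁻³, …, 10⁴} by tuning-fold accuracy, and the held-out fold is
scored. Feature z-scoring, two-sample-t feature selection (default
α = 0.05; if nothing passes, the single best column is kept) and, when
requested, the per-ROI PCA are all refitted inside every training
partition. The rotation is repeated (default 100×) with re-randomised
stratified folds; accuracy, sensitivity and specificity are means over
repeats, and the ROC/AUC is computed from each subject's mean out-of-fold
decision value (the AUC equals the Mann–Whitney concordance probability).
Significance uses permutation testing: the full nested CV is rerun on
label-shuffled data (default 100×) and

    p = (1 + #{permuted accuracy ≥ observed}) / (1 + n_permutations),

the add-one Monte-Carlo estimator, so p is never 0 and 100 permutations
bottom out at 1/101 ≈ 0.0099. Accuracy distributions of two measures are
compared with a paired t-test when they share fold seeds (Welch otherwise).
Tuning-grid ties resolve to the first entry in the fixed kernel-then-C
order. Reported accuracy is the plain proportion correct; no class
reweighting.

## Concordance and contribution

Two classifiers are compared by (a) the Jaccard coefficient
|A∩B| / |A∪B| between their sets of correctly classified subjects
(J = 1 when both sets are empty; an alternative on predicted-positive sets
is available) and (b) Cohen's kappa (Pr(a) − Pr(e)) / (1 − Pr(e)) between
their predicted-label vectors, treating the classifiers as raters. The
per-subject prediction is the majority out-of-fold vote over repeats, ties
going to the positive class with a warning.

Modality contribution fits a logistic regression
log(p/(1−p)) = Xᵀβ on each modality block and on the fused block (all
ROIs' columns of that modality pooled into one design matrix), and
summarises each fit by the Cox–Snell index

    R² = 1 − exp(2(ℓ₀ − ℓ₁)/n),

with the contribution of a modality defined as R²_modality / R²_fusion.
Fits use damped Newton iterations with a backtracking line search;
convergence requires gradient max-norm < 10⁻⁸, with a stalled-progress
fallback that accepts the point when the objective can no longer improve at
float precision and the gradient is below 10⁻⁵·max(1, |ℓ|). The intercept
is never penalised, and R² is always computed from the plain (unpenalised)
log-likelihood at the fitted coefficients, whatever the penalty. At ridge 0
a quasi-separated fit is detected (huge, perfectly separating slope vector)
and reported as an error — at fusion width (94 features per ROI × 90 ROIs
against a few hundred subjects) separation is the rule, so the default
ridge is 10⁻⁴ and a larger value is advisable for small cohorts.

## Synthetic cohorts

No public dataset accompanies the method, so validation runs on synthetic
two-group cohorts with known injected effects. The generator is
deliberately simple and fully documented rather than biophysically
realistic:

* **Time series**: Cholesky colouring of i.i.d. standard-normal
  innovations against a target ROI×ROI correlation matrix (default:
  constant off-diagonal ρ = 0.1, a weak exchangeable baseline). Draws are
  independent across time — no temporal autocorrelation, haemodynamics,
  band-pass structure, motion or scanner noise. Defaults: 160 subjects per
  group, 90 ROIs, 200 timepoints.
* **Scalars**: per-ROI Gaussians. Baselines (mean, SD): GM 7.5 ± 1.0 cm³,
  WM 5.0 ± 0.8 cm³, FA 0.40 ± 0.04, RD 0.60 ± 0.05 and MD 0.80 ± 0.05
  (10⁻³ mm²/s) — values in the range reported for adult AAL parcellations;
  downstream stages are scale-invariant after z-normalisation, so only the
  effect sizes in SD units matter.
* **Effects**: scalar effects shift the group-2 mean at a chosen ROI by d
  SDs; connectivity effects edit the group-2 target correlation matrix
  (rejected if the edit breaks positive definiteness), so the Fisher-z
  pipeline is exercised end to end rather than shifting features post hoc.
* **Reproducibility**: one global seed fans out to per-subject streams
  keyed by (group, index), so enlarging the cohort never reshuffles
  existing subjects.

Consequently, passing tests demonstrate correctness of the statistics and
the absence of information leakage under a Gaussian, temporally white,
exchangeable-correlation world; they do not certify behaviour under
realistic BOLD autocorrelation, registration error or site effects.

## Validation design and problem sizes

The acceptance checks (in `tests/test_acceptance.py`, recomputed by
`scripts/acceptance.py`) were sized to run comfortably on a single CPU:

* worked examples on a case–control cohort's demographic table (pooled t
  on mean ± SD summaries, 2×2 chi-square) checked at the printed
  precision;
* Wilks λ against statsmodels' MANOVA on 50 seeded instances (n = 40,
  m ≤ 5, G ∈ {2,3}) to 10⁻⁸, and T = W + B to 10⁻¹⁰;
* the m = 1 reduction λ = 1/(1 + t²/(n−2)) exactly, and Bartlett vs.
  pooled-t p within 0.005 at n = 2000;
* type-I calibration on 2000 null synthetic ROIs (250 cohorts × 8 ROIs,
  100 per group), rejection rate inside the exact binomial 99% interval
  around 0.05;
* effect recovery: d = 1.0 on GM and FA at one ROI, 150 per group, 90
  ROIs, 50 replicates — the affected ROI must attain the smallest fusion p
  in ≥ 90% of replicates and the fusion p must beat every single-modality
  p there in the majority. The recovery check uses the PCA-reduced fusion
  vector (10 features): with a two-feature scalar signal, the full
  94-feature vector spends 89 chi-square degrees of freedom on null FC
  dimensions, and a straightforward noncentrality argument shows the
  2- and 3-feature single-modality measures then dominate it — so the
  reduced variant is the one for which the fusion-dominance claim is the
  analytically correct expectation;
* classifier harness: null permutation p approximately uniform (20
  replicates × 50 permutations at reduced repeats), mean nested-CV
  accuracy ≥ 0.95 on classes with total Mahalanobis separation 4 (Bayes
  accuracy ≈ 0.977), AUC equal to exhaustive pair counting;
* concordance/contribution: brute-force set enumeration for J and K,
  Cox–Snell R² against statsmodels likelihoods to ~10⁻⁸, and the
  signal-bearing modality attaining the largest contribution ratio in
  ≥ 80% of 25 replicates.

## Known limitations

* The generator's distributional choices are the package's own; nothing in
  the method constrains them.
* Bartlett's chi-square is an asymptotic approximation; at small n relative
  to m its p-values are only approximate (the implementation refuses the
  regime where its scale factor is non-positive).
* Only binary group designs are supported end to end (the MANOVA layer
  itself accepts G > 2).
* Voxel-level preprocessing, tensor fitting from raw diffusion volumes and
  atlas handling are out of scope: the package starts from ROI-level
  tables.
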