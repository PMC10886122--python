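# Methods

This note records the modeling choices behind `aba-subtypes`: what each
stage assumes, which parameters matter, how the synthetic testbed is
calibrated, and where the design was genuinely open.

## Brain-age models

One L1-penalized linear regression (Lasso) per modality maps that
modality's IDP block to chronological age. Features are standardized
with training-set mean/SD (constant features dropped and recorded);
the penalty is selected from the fixed grid {0.001, 0.01, 0.1, 1, 10,
100} by 5-fold cross-validation minimizing MAE, with ties broken toward
the larger penalty (prefer the sparser model when performance is
indistinguishable). The three modalities are modeled independently —
each block carries its own aging signal and its own noise, and
per-modality BrainAGE signs are what stratification consumes.

**Age-bias correction.** Regression toward the mean makes raw predicted
age too old for young subjects and too young for old ones. We fit the
OLS line `predicted_raw ≈ α + β·age` on the training set only and apply
it unchanged to test subjects. Two readings of the corrected value are
supported via `correction_mode`:

- `residual` (default): `corrected = raw − α − β·age` is a *deviation*
  in years and is used directly as BrainAGE. On the training set it has
  mean 0 and exactly zero correlation with age (OLS orthogonality);
  the stratification step needs only its sign.
- `rescale`: `(raw − α)/β` is a corrected *predicted age*; BrainAGE is
  then `corrected − age`. Requires |β| > 1e−8.

The default is `residual` because the corrected quantity feeds directly
into sign-based stratification and group-level BrainAGE summaries,
where a zero-centered, age-orthogonal deviation is the interpretable
object.

## Stratification

ABA ⇔ BrainAGE strictly positive in all three modalities; RBA ⇔
strictly negative in all three; everything else MIXED. Exact zeros are
a measure-zero event and fall to MIXED (strict inequalities — no tie
rule is needed beyond this convention). Under independent symmetric
modality errors each one-sided group has probability (1/2)³ = 0.125,
which the tests verify at n = 2000. Stratification is performed within
the test split only; the training split exists to fit the predictive
models and the bias line.

## HYDRA: max-margin polytope clustering

The ABA group (targets) is separated from the RBA reference (controls)
by K linear classifiers forming a convex polytope. Each face j is a
soft-margin squared-hinge classifier; its training set is **all**
controls (label −1, per-sample weight 1/K, so total control influence
is constant in K) plus the targets currently assigned to j (label +1,
weight 1). The joint objective is

    Σ_j [ ½(‖w_j‖² + b_j²) + C Σ_i s_i max(0, 1 − y_i(w_j·x_i + b_j))² ].

Fitting alternates estimation (refit each face) with assignment (each
target moves to the face with its largest decision value). Both steps
are monotone in the objective, which is recorded per iteration;
convergence is an assignment pass that changes nothing (`max_iter` 50).
An assignment pass that empties a face reseeds it with the globally
worst-fitting target. With K = 1 the procedure reduces exactly to a
single weighted linear max-margin classifier.

**Base solver.** The squared-hinge primal is smooth, so we minimize it
directly with L-BFGS (analytic gradient, `ftol` 1e−6 inside the
alternating loop, tighter where tests need it). This supports arbitrary
per-sample weights and — crucial for speed — warm starts: after the
first iteration each face refit starts from its previous hyperplane and
costs milliseconds. The intercept is L2-regularized along with the
weights (equivalent to an always-on unit feature), which is harmless
after feature standardization and keeps the objective strictly convex.

**Covariate residualization.** Before clustering, age, sex and
education years are regressed out of every feature with OLS fitted on
the *reference group only*, applied to everyone, and residuals are
standardized by the reference-group residual SD. Fitting on the
reference group means target-specific deviations are not absorbed into
the nuisance model. Residualization is preprocessing, not part of the
loss — the simplest arrangement that keeps the polytope objective
unchanged.

**Initialization.** Candidate aging directions are unit-normalized
(target − control centroid) vectors for a random pool of targets
(default 50). A K-subset is chosen by greedy maximization of the
determinant of the candidates' similarity kernel — a deterministic
k-DPP approximation — then polished to single-swap local optimality.
The kernel is the entrywise *square* of the Gram matrix (still PSD, by
the Schur product theorem): diversity should measure collinearity
irrespective of sign, so two antipodal aging directions are "the same
axis" for selection while the signed-cosine assignment still separates
them. Each target initially joins the direction of largest cosine
similarity.

In high dimension, raw deviation vectors are noise-dominated (a
1.5-SD offset spread over 561 coordinates has cosine ≈ 0.1 with its own
direction), and the alternating polytope optimization cannot repair a
near-random start: once per-face target counts are comparable to the
feature dimension, each face separates its own targets linearly and
every assignment becomes a fixed point. Initialization quality is
therefore decisive, and three refinements are applied when the ambient
dimension exceeds the candidate-subspace size:

1. directions are measured in a **control-whitened metric** (eigenvalue
   shrinkage 0.05 of the mean eigenvalue), which cancels variance
   directions shared with controls, e.g. block noise factors;
2. candidates are projected onto the **leading principal components of
   the whitened target deviations** (max(K, 2) components), where
   between-subtype structure concentrates;
3. the initial labels are refined by spherical-mean rounds in that
   subspace, then by unit-variance **soft-EM rounds on the full
   whitened deviations** — centroids average away subject noise, and
   soft responsibilities avoid the boundary bias of hard reassignment.

The polytope fit then starts from labels near the discriminative
optimum and its margin machinery determines the final model. All steps
are deterministic given the seed.

**Consensus fusion.** `n_init` (default 10) independently initialized
fits are fused through the co-assignment matrix (fraction of runs in
which two subjects share a cluster); average-linkage hierarchical
clustering of 1 − co-assignment cut at K gives the fused labels, from
which one final polytope fit is run. A single run passes through
unchanged.

**Model-order selection.** For each K in 2..5, the targets are split
into five folds; each fold's training portion (plus all controls) gets
a full fused fit, and stability is the mean pairwise ARI between fold
solutions on the targets their training sets share. The selected K
maximizes mean stability, ties toward smaller K (prefer the simpler
model). K = 1 is excluded — single-cluster partitions make the ARI
degenerate. Final labels come from a full-data fused fit at the
selected K: deterministic, and every target receives a label (fold
consensus would leave held-out assignments to chance overlaps).

## Characterization statistics

Z-scores use the RBA reference moments (`(x − mean_RBA)/sd_RBA`), so the
reference group sits at 0 by construction; group means are reported
with 95% CIs as mean ± 1.96·SD/√n on the Z scale. ANOVA across
RBA + subtypes runs per IDP on covariate-adjusted values (pooled OLS
residuals on age, sex, education; an unadjusted mode exists); the
Bonferroni rule flags raw p < q/m with q = 0.01 and m = number of IDPs
(561 in the full schema ⇒ cutoff ≈ 1.78e−5). "Bonferroni at q" is read
literally as the family-wise rule, not FDR. Cognitive scores: the two
duration-valued tests (reaction time, trail making) are natural-log
transformed (values must be positive), then ANOVA plus Dunnett
many-to-one contrasts against the declared reference (default RBA) and
Dunnett-family contrasts among subtypes, flagged at p < 0.05. Dunnett
p-values come from scipy's multivariate-t implementation with a fixed
random state, making reports deterministic. Categorical lifestyle
variables use chi-square on group × category tables without continuity
correction (matching the plain Σ(O−E)²/E statistic).

## Synthetic cohort generator

The generator emulates exactly the statistical structure the analysis
relies on, with known ground truth:

- ages uniform on 45–83; sex Bernoulli(½); education ≈ N(16, 3²) years;
- per IDP: value = baseline + scale·z with z = slope·(age − midpoint) +
  covariate effects + noise; slopes average `age_slope_scale`
  (default 0.02 SD/year, mostly negative — features degrade with age);
- noise combines an independent term with a shared per-block factor
  (`block_noise_corr`, default 0.1) so modality blocks are internally
  correlated;
- a fraction `aba_fraction` (default 1/3) of subjects carries one of K
  (default 3) planted subtype offsets: mutually orthogonal unit
  directions in standardized IDP space scaled by `subtype_effect_size`
  (default 1.5 SD);
- cognitive scores decline linearly with subtype severity; the two
  duration tests are generated on a positive (log-normal) scale;
- lifestyle variables mix quantitative (blood pressure, grip strength,
  driving time) and categorical (walking pace, diabetes) columns.

`noise_sd` defaults to 1/3 SD, making the planted offsets about 4.5×
the residual noise (pairwise centroid separation ≈ 6 noise SDs). This
is a deliberate *testability* calibration: the generator's job is to
verify that each stage recovers structure that is present by
construction. At noise levels where the planted separation approaches
the Bayes limit of any assignment rule (≈1 SD noise at this effect
size), no algorithm could meet a high recovery bar, so a failure there
would measure the testbed, not the code. Planted subtype directions are
random and therefore essentially orthogonal to the aging axis: planted
accelerated agers do *not* systematically show positive BrainAGE, and
sign-stratification of a synthetic test set behaves as under the null
(~12.5% ABA). Recovery experiments accordingly cluster the planted
groups directly. What passing tests show is that the machinery is
correct under its own assumptions; they say nothing about effect sizes,
non-linear age trajectories, scanner/site effects, or missingness
patterns of real cohorts, none of which the generator attempts.

## Numerical and reproducibility choices

- Every source of randomness flows from explicit integer seeds;
  per-stage sub-seeds derive from a single `SeedSequence`, so stages
  are independently re-runnable and full runs are file-identical
  (SHA-256 manifest).
- Assignment argmax ties break toward the lowest face index; penalty
  ties toward stronger regularization; stability ties toward smaller K.
- Degenerate inputs fail loudly: constant reference features, collinear
  covariates, empty groups, mismatched IDs, non-positive values under a
  log transform.
- Problem sizes: the test suite exercises the full 561-IDP schema where
  the schema itself matters (generator invariants, family-wise error
  control at m = 561, the n = 3000 recovery study with K ∈ 2..5
  stability) and reduced blocks (15–70 IDPs) elsewhere; stability CV
  inside tests and the acceptance script uses 2 fused initializations
  per fold with 5 for final fits. These sizes are the package's default
  experiment design; all scale up through configuration.

## Known limitations

- Only linear max-margin faces; no kernels, no soft final assignments.
- The k-DPP is approximated by greedy determinant maximization with
  swap polishing, not exact sampling.
- Dunnett contrasts among subtypes reuse the many-to-one machinery per
  control group rather than a single all-pairs family.
- The education covariate is taken as years directly; mapping from
  survey codes is out of scope.
- The generator plants linear age effects and Gaussian noise; real IDP
  distributions are heavier-tailed and age trajectories non-linear.
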