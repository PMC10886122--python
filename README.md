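# aba-subtypes

Dissecting the heterogeneity of **accelerated brain aging (ABA)** from
multimodal imaging-derived phenotypes (IDPs).

Brains do not age uniformly: some people's imaging features look older
than their chronological age (accelerated agers, ABA), others younger
(resilient agers, RBA), and the accelerated group itself is a mixture of
distinct aging patterns. This package implements, as a tested and fully
reproducible pipeline, the analysis needed to find and describe those
patterns in a tabular cohort of subjects × IDPs:

1. **Brain-age prediction.** One Lasso model per imaging modality
   (sMRI: 207 gray-matter volume / cortical thickness features; dMRI:
   144 FA/MD/ISOVF tract means; rsfMRI: 210 network edges — 561 IDPs in
   total), penalty chosen from the grid {0.001, 0.01, 0.1, 1, 10, 100}
   by cross-validated MAE on a 40% training split.
2. **Age-bias correction.** Raw predictions regress toward the mean, so
   the training-set regression of predicted on chronological age
   (intercept α, slope β) is removed:
   `corrected = predicted_raw − α − β·age`.
   The corrected value is the **BrainAGE** (brain-age gap); by OLS
   orthogonality it has mean 0 and zero age-correlation on the training
   set.
3. **Stratification.** Test-set subjects with BrainAGE > 0 in **all
   three** modalities are ABA; < 0 in all three, RBA; anything else
   MIXED.
4. **HYDRA subtyping.** A from-scratch semi-supervised max-margin
   polytope clustering of the ABA group against the RBA reference: K
   linear squared-hinge classifiers (faces) jointly enclose the
   controls, each ABA subject is assigned to the face with its largest
   decision value, and estimation/assignment alternate until a fixed
   point. Nuisance covariates (age, sex, education years) are regressed
   out against the reference group first. Initialization samples
   mutually diverse aging directions (greedy k-DPP), multiple
   initializations are fused by co-assignment consensus, and the number
   of subtypes K ∈ {2..5} is selected by five-fold cross-validated
   stability measured with the adjusted Rand index (ARI).
5. **Characterization.** Every IDP is expressed as a Z-score against the
   RBA reference (RBA ≡ 0), compared across groups by covariate-adjusted
   ANOVA with Bonferroni control at q < 0.01 over all 561 IDPs; the nine
   cognitive tests (duration-valued ones log-transformed) by ANOVA +
   Dunnett contrasts at p < 0.05; categorical lifestyle variables by
   chi-square.

Real cohorts of this shape come from access-controlled biobanks, so the
package ships a first-class **synthetic cohort generator** that plants
the structure the analysis assumes — linear age effects per IDP,
modality-block noise, and K orthogonal subtype offset directions — with
known ground truth, which the test suite uses to verify every stage
end to end.

## Worked example

```python
from aba_subtypes import (
    GeneratorConfig, generate_cohort, split_cohort, fit_brainage_model,
    predict_brainage, evaluate_mae, stratify, stratification_summary,
    residualize_covariates, cluster_stability, fit_hydra, adjusted_rand_index,
)

cohort, truth = generate_cohort(GeneratorConfig(n_subjects=2000, seed=1))
train, test = split_cohort(cohort, train_fraction=0.40, seed=1)

results = {}
for modality in cohort.schema.modality_blocks:
    model = fit_brainage_model(train, modality, seed=1)
    res = predict_brainage(model, test)
    results[modality] = res
    mae = evaluate_mae(res.predicted_raw, res.chronological_age)
    print(f"{modality}: penalty={model.penalty}, test MAE {mae:.2f} y")

groups = stratify(*(results[m].brainage_series() for m in ("sMRI", "dMRI", "rsfMRI")))
print(stratification_summary(groups))

ids = cohort.subject_ids.to_numpy()
is_aba = truth.aba_flag.loc[ids].to_numpy()
feats = residualize_covariates(
    cohort.idp_matrix(), cohort.covariate_matrix(), reference_mask=~is_aba,
    feature_names=cohort.schema.idp_columns,
)
curve = cluster_stability(feats, is_aba, k_range=(2, 3, 4, 5), n_init=2, seed=1)
print({k: round(v, 3) for k, v in curve.mean_ari.items()}, "-> K =", curve.selected_k)

model = fit_hydra(feats, is_aba, K=curve.selected_k, n_init=5, seed=1)
ari = adjusted_rand_index(model.assignments, truth.labels_for(ids[is_aba]) - 1)
print(f"recovered subtypes vs planted truth: ARI {ari:.3f}")
```

Output:

```
sMRI: penalty=0.1, test MAE 1.93 y
dMRI: penalty=0.01, test MAE 2.13 y
rsfMRI: penalty=0.1, test MAE 1.74 y
{'ABA': 172, 'RBA': 165, 'MIXED': 863}
{2: 0.615, 3: 0.969, 4: 0.696, 5: 0.574} -> K = 3
recovered subtypes vs planted truth: ARI 0.951
```

Reading the output: each modality's Lasso predicts age to ~2 years MAE
on held-out subjects (the mean-age predictor sits near 9.5 years).
Roughly an eighth of the test set shows a positive BrainAGE in all
three modalities and an eighth a negative one — planted subtype
directions are orthogonal to the aging axis, so sign-consistency is
noise-driven here, as it would be under the null. Stability is maximal
at K = 3, matching the three planted subtypes, and the fused full-data
labels recover the planted partition almost exactly (ARI 0.95).

The same pipeline runs from the shell:

```bash
aba-subtypes run --seed 7 --out my_run        # simulate → … → characterize
aba-subtypes simulate --n-subjects 2000 --seed 1 --out data/
aba-subtypes brainage --cohort data/cohort.csv --train-fraction 0.4 --seed 1
```

Every run writes its artifacts (cohort, fitted models, predictions,
labels, stability curve, report tables) plus a manifest with SHA-256
checksums; identical configuration and seed reproduce identical files.

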