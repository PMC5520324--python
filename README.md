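# painfusion

Tools for fusing randomized-trial and observational longitudinal pain data
into a single predictive platform, built around the published analysis
pipeline for pregabalin response in painful diabetic peripheral neuropathy
(pDPN): hierarchical clustering of a large observational cohort, coarsened
exact matching (CEM) of RCT patients into the clusters, per-cluster ARX
calibration of weekly pain scores, and validation of responder prediction
on the patients that never matched.

The intended users are biostatisticians and health-outcomes researchers who
want to run, test or extend this kind of RCT–observational data fusion.
Because the original patient-level datasets are confidential, the package
ships a synthetic-cohort generator that reproduces the statistical
structure the analysis assumes, so every stage is runnable and testable
end to end.

## The method

1. **Clustering.** Observational patients are clustered by Ward's
   minimum-variance method on nine baseline variables (gender, age, pDPN
   duration, BMI, depression history, pregabalin monotherapy, prior
   gabapentin, baseline pain, baseline sleep interference), all columns
   standardized. The cluster count *k* is chosen from the semipartial
   R² of each merge, spr²(m) = ΔSSE(m) / SS_total: scanning from the top of
   the tree, *k* is the first cluster count whose forming merge has
   spr² < 0.05.

2. **Matching.** Within each cluster, CEM coarsens the matching variables
   (sex; age 0–44/45–64/65–74/75+; BMI normal/overweight/obese; baseline
   pain and sleep 0–3/4–5/6–7/8–10), stratifies both groups on the joint
   bins, and keeps only strata containing patients from both sources.
   Balance is scored by the multivariate L1 imbalance
   ½ Σ_cells |f − g| (0 = identical distributions, 1 = disjoint), reported
   before and after matching.

3. **Calibration.** For each cluster, weekly pain y(t) is modelled as a
   linear lagged regression

       y(t) = c + a₁·y(t−1) + a₂·y(t−2) + b·sleep(t−1)
              + d₀·dose(t) + d₁·dose(t−1) + d₂·dose(t−2)
              + exogenous patient terms + ε(t),   ε ~ N(0, σ²),

   with inputs named x1..x13 (pain lags, sleep lag, dose lags, insulin,
   monotherapy, gender, age cohort, pDPN duration, lag-1 feeling items).
   Terms are chosen by forward/backward partial-F selection and fit by
   Gaussian maximum likelihood; fits report R², RMSE, log-likelihood and a
   likelihood-ratio test.

4. **Prediction and validation.** Fitted equations are iterated forward to
   predict trajectories and responder status (responder level =
   (baseline − pain(t)) / baseline, thresholds 50% / 30%), with ROC/AUC per
   cluster and observed-vs-predicted t-tests on the unmatched patients.

## Worked example

```python
import painfusion as pf

cfg = pf.CohortConfig(n_obs=400, n_rct=120, seed=7)
cohort, panel = pf.generate_cohort(cfg)
obs = cohort[cohort["arm"] == "observational"].reset_index(drop=True)

# Ward tree + semipartial-R2 cut
sol = pf.ward_cluster(pf.encode_features(obs))
pf.semipartial_r2(sol)
pf.cut_by_spr2(sol, threshold=0.05)
print("clusters:", sol.k)
print("sizes:", sol.assignment.value_counts().sort_index().to_dict())

# CEM of all RCT patients into cluster 1
rct = cohort[cohort["arm"] == "rct"]
members = sol.assignment.index[sol.assignment == 1]
md = pf.match_cluster(cohort[cohort["patient_id"].isin(members)], rct,
                      cluster_id=1)
print(f"cluster 1: {md.obs_after}/{md.obs_before} observational patients "
      f"matched, {md.rct_matched} RCT patients")

# interpolate the missing observational weeks, then calibrate
panel_c = pf.interpolate_panel(panel)
model = pf.PainARXModel.from_panel(panel_c, cohort, pf.DEFAULT_SPEC,
                                   patients=md.matched_ids, cluster_id=1)
res = pf.stepwise_select(model, alpha=0.05)
print("selected terms:", res.model.spec.terms)
print(f"R2 = {res.rsquared:.3f}, RMSE = {res.rmse:.3f}, "
      f"LR p = {res.lr_pvalue:.2e}")
```

prints

```
clusters: 6
sizes: {1: 87, 2: 58, 3: 58, 4: 79, 5: 56, 6: 62}
cluster 1: 43/87 observational patients matched, 26 RCT patients
selected terms: ('x1', 'x11', 'x13')
R2 = 0.842, RMSE = 0.463, LR p = 3.86e-86
```

The six-component synthetic cohort is recovered at the 0.05 semipartial-R²
cutoff; about half of the cluster's observational patients find a coarsened
exact match; and the stepwise fit keeps the lag-1 pain term (the dominant
predictor), the pDPN-duration term and a feeling item, with fit quality in
the high-R², sub-half-point-RMSE regime that weekly pain scores support.

The same pipeline runs end to end from a config:

```
painfusion run --out results/run --n-obs 3159 --n-rct 398 --seed 1
```

writing `cohort.csv`, `panel.csv`, `clusters.csv`, `matched.csv`,
`imbalance.csv`, `armax_fits.json`, `validation.csv`, `loglik.csv` and a
`manifest.json` with seeds and patient accounting for every stage.

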