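# Methods

This note documents the models and procedures implemented in painfusion,
the design choices made where the published analysis left details open,
and what the synthetic cohort does and does not emulate.

## Synthetic cohort

The generator emulates two data sources: a large observational pDPN cohort
(weekly pain/sleep measured at weeks 0, 1, 3, 6; weeks 2, 4, 5 missing)
and a smaller fixed-dose RCT cohort observed every week. Patients are
drawn from a six-component mixture of cluster profiles defined in
`src/painfusion/data/cluster_params.yaml` (version 1).

**Covariates.** Continuous variables (age, BMI, pDPN duration, baseline
pain, baseline sleep) are truncated normals per cluster; binary flags
(gender, depression history, monotherapy, prior gabapentin, insulin) are
Bernoulli at the profile rates. The published per-cluster binary rates and
within-cluster SDs are kept. The continuous *means*, however, are spread
apart across clusters (cluster 1 leanest and youngest, cluster 3 oldest,
cluster 2 longest disease duration, cluster 6 most severe pain and sleep
interference — preserving the published ordering). This is deliberate: the
published profiles alone do not define six mutually separable components,
because two of the profiles differ mainly in variables that are not
clustering inputs (e.g. insulin use), and a generator sampling independent
marginals from them yields four to five Ward-recoverable groups, not six.
Since the generator's contract is to produce a six-component cohort that
the clustering stage can recover, the centroid spread was fixed once, from
a separability experiment, before the acceptance suite was written, and is
versioned in the parameter file. Users who want strictly profile-faithful
(but non-separable) marginals can supply their own parameter file.

**Trajectories.** Weekly pain follows the six reference ARX equations
(`painfusion.equations.CLUSTER_EQUATIONS`) plus Gaussian noise with the
published per-cluster residual scales (0.53–0.57 pain-score units), then
clipping to [0, 10]. Lags reaching below week 0 use baseline-carry for
pain and 0 for dose (the least-informative choice; the source is silent).
Auxiliary processes:

- **sleep(t)** = α_c + 0.9·pain(t) + N(0, 0.6), clipped to [0, 10], with
  α_c anchoring the cluster's baseline sleep mean. This reproduces lag-0
  pain–sleep cross-correlations of ~0.85, matching the ≥0.70 values the
  published cross-correlation table reports.
- **dose** follows a titration ladder 75 → 150 → terminal mg from week 2
  (fixed dose in the RCT arm), with terminal doses drawn from the
  per-cluster published frequencies. Doses stay in mg; the dose
  coefficients are therefore on the ~10⁻³ scale and directly comparable
  to the reference equations.
- **feeling items** (full of energy, calm and relaxed, discouraged) are
  six-state sticky chains (stay probability 0.6, otherwise ±1 step) started
  from the published baseline frequencies. The always-to-never scale is
  coded 1 = always … 6 = never; the source does not state its coding, so
  this convention is fixed here and used consistently.

**What the generator does not emulate:** adverse events and dropout
(excluded from the source analysis by design), real within-cluster
covariate dependence, measurement rounding of 0–10 scores to integers, and
any treatment-assignment mechanism (dose is exogenous by construction).
Consequences: passing tests show the *pipeline machinery* is correct under
the stated data-generating assumptions; they say nothing about whether
real pDPN data satisfy those assumptions.

## Interpolation

Missing weeks are filled by local second-order (piecewise quadratic)
interpolation: each missing week is interpolated through the three nearest
observed weeks (ties to the earlier week), reproducing any quadratic trend
exactly. A missing boundary week is extrapolated from the nearest three
points and flagged. Filled values are clipped to [0, 10]. Patients with
fewer than three observed weeks raise an error naming the patient;
patients still incomplete after interpolation are excluded from
calibration. Interpolation smooths the noise at filled weeks, which is
why full-pipeline fits on interpolated panels show slightly lower RMSE
than the generating noise SD.

## Clustering

Ward's minimum-variance linkage (scipy backend) on the nine clustering
variables. All columns — binary flags included — are standardized to unit
variance before clustering; with only the continuous columns standardized,
a flag flip would amount to one within-column SD and the therapy/history
flags would carry almost no weight against five continuous columns of
noise. The semipartial R² of merge *m* is ΔSSE(m)/SS_total = h²_m / (2·SS_total)
(h = Ward height); the sequence sums to 1. The cluster count is the first
*k* (from the top of the tree) whose forming merge has spr² below the
threshold (default 0.05); if no merge qualifies every point is a
singleton. Merge heights are asserted nondecreasing on every run, and the
implementation is checked against an independent O(n³) Ward oracle in the
tests (ties excluded; scipy's nearest-neighbor-chain tie order is the
package's deterministic tie rule).

## Coarsened exact matching

Default matching variables: sex, age group, BMI class, baseline pain bin,
baseline sleep bin, with the published table bins as the coarsening (the
source never lists its CEM variable set or bin edges explicitly; these
defaults are this package's documented choice and are overridable). A
stratum is matched iff it contains at least one patient from each group.
Matched RCT patients get weight 1; matched observational patients get the
standard CEM weight (m_rct,s / m_obs,s) · (M_obs / M_rct), which reweights
the observational strata toward the RCT stratum distribution. Weights are
emitted but calibration uses unweighted matched patients (the source
states no weighting). The L1 imbalance is computed on the coarsening bins
by default (whether the published imbalances used coarsened bins or raw
covariates is unstated); on those bins matching can only remove
mass-mismatched cells, so L1 after ≤ L1 before holds and is asserted.

## ARX calibration

The reference equations contain no moving-average error terms, so the
model family is ARX — a linear regression of pain(t) on lagged pain,
lagged sleep, current/lagged dose, lagged feeling items and patient-level
exogenous terms — despite the ARMAX name used in the source field.
Gaussian maximum likelihood coincides with least squares; the
implementation delegates to statsmodels OLS and is oracle-checked against
explicit normal equations. Design rows are patient-weeks with all required
lags available (t = 2..6 for lag-2 specs), so the week-0 bootstrap
conventions never enter the estimation. RMSE is √(SSE/n) on the
calibration rows (not n−p), matching the ML residual scale. Stepwise
selection enters candidates by descending partial F (p < α to enter,
ties by the canonical x1..x13 order), then backward-eliminates terms with
p ≥ α. Trajectory prediction iterates one-step predictions with predicted
pain feeding the lags (a one-step-ahead mode using observed lags is
available and is what the fit metrics correspond to); predictions are
clipped to [0, 10].

Identifiability note: the dose lags are identified by the titration ladder
(weeks 0–3 transitions). In a fixed-dose-only sample (RCT arm alone) the
three dose columns are collinear and the fit correctly refuses with a
singular-design error naming them.

## Validation

`ttest_obs_vs_pred` is Student's two-sample pooled-variance t-test by
default, following the source's wording, with a paired mode behind a flag.
The two variants answer different questions. Observed and predicted final
pain are strongly positively correlated across patients (they share the
baseline), so the two-sample test's standard error is roughly twice the
true SE of the mean difference: as a model check it is conservative by
construction (empirically ~0 rejections per 100 well-specified
replicates). The paired test removes the shared variance and is the
variant that is type-I calibrated (~5% rejections at α = 0.05 under
generator = fitted model); the calibration test in the acceptance suite
therefore uses the paired mode, while the reporting tables keep the
two-sample default.

Two further caveats the full-pipeline validation inherits by design.
First, "pain level among responders" conditions on the observed outcome
(selection on noise), so observed pain among observed responders is
systematically below its noise-free prediction; the conditioning side is
switchable (`condition_on`). Second, predicted responder levels are
noise-free while observed levels carry residual noise, so
threshold-crossing *rates* can differ even under a correct mean model,
and estimated (Ward) clusters mix generating equations, making the
per-cluster model an average. On large synthetic runs these effects make
the validation t-tests reject — the tests have genuine power against
cluster impurity — which is the expected behaviour of the synthetic
study, not a defect of the machinery.

The before/after log-likelihood comparison fits the same multinomial logit
of binned baseline pain (published score bins) on the matching variables
in the pre-CEM cluster sample and in the matched sample, and reports both
log-likelihoods with a chi-square comparison, reproducing the source
procedure literally. Log-likelihoods from samples of different sizes are
not strictly comparable — a smaller matched sample raises the
log-likelihood for sample-size reasons alone — so this diagnostic should
be read qualitatively.

## Problem sizes and tolerances

Defaults used by the shipped checks, chosen as desk-scale study
conditions: coefficient-recovery runs use 2000 patients per cluster
(10 000 patient-week rows) at the published residual scales; zero-noise
round-trips use 150 patients and demand recovery to 10⁻⁶ or better;
Ward-oracle equivalence uses 30–50-point instances at 10⁻⁹ height
tolerance; cluster-count stability uses 20 seeds at 500 observational
patients; type-I calibration uses 100 replicates of 40 validation
patients. Numerical tie-breaks: stepwise ties by term order; cut labels
relabelled 1..k in order of first appearance; all randomness flows from a
single integer seed through numpy SeedSequence spawning.

## Known limitations

- The six reference equations are treated as exact generative truths; the
  package does not attempt to re-derive them from the original data,
  which are not public.
- The separability-driven centroid spread (above) means the default
  synthetic profiles are stylized, not a literal emulation of the
  published cluster table.
- CEM variable set, bin edges, L1 evaluation grid and the feeling-scale
  coding are documented package choices where the source is silent.
- The agent-based follow-on modelling and safety/discontinuation analyses
  of the source programme are out of scope.
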