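# Methods

## Outcome coding

Blood pressure is classified by the conventional five-group definitions
(normal; elevated; high stage 1; high stage 2; hypertensive) and coded
ordinally 1–5. Read as joint conditions on (systolic, diastolic), those
definitions neither cover the plane — (125, 85) matches no group — nor
partition it — (150, 125) matches two. We therefore classify each component
separately against its own bands (systolic: <120, 120–129, 130–139, 140–180,
>180; diastolic: <80, 80–89, 90–120, >120, with no diastolic "elevated"
band) and return the more severe code, the usual clinical higher-category
rule. The map is total over the physiologic plane and monotone in each
component, and it agrees with every printed band on readings that band
covers; both properties are verified by an exhaustive 1-mmHg grid sweep in
the tests. A 4-level display coding collapses {elevated, high stage 1} into
"prehypertension" ({1}→1, {2,3}→2, {4}→3, {5}→4); the binary outcome is
"high" iff the 4-level code exceeds 1. Both collapses are configurable.
Regression defaults to the 5-level code; the network classifier defaults to
the 4-level code.

## Feature reduction

Greedy randomized pivot clustering on the absolute Pearson correlation:
repeatedly draw a uniform-random pivot from the surviving pool (one seeded
generator for the whole run), move every surviving feature with |r| > t into
the pivot's cluster, and recurse on the remainder. The strict inequality is
kept verbatim, so |r| exactly equal to t does not join. Defaults: t = 0.45.
Consequences asserted as invariants: clusters partition the feature set,
every member exceeds t against its pivot, and any two pivots are ≤ t apart.

Numerical choices: correlations use pairwise-complete observations with a
minimum overlap of 10 samples, below which a pair is treated as
uncorrelated; zero-variance features have undefined correlations and are
placed in singleton clusters. The representative of a cluster is its pivot —
the only member guaranteed correlated with every other member. Reduction is
fit on the discovery cohort and the resulting representative set is applied
unchanged to the validation cohort, avoiding validation leakage; pooling the
cohorts for reduction is available but not the default.

## Association model

Per-feature OLS with the blood-pressure code treated as a continuous
response (the published analyses report single linear estimates per
metabolite, which an ordinal model would not produce). Screening model:
`bp ~ feature + ckd_stage + feature:ckd_stage`, significance read from the
feature main effect with the interaction present. The interaction column is
the product of *mean-centered* factors: with raw all-positive LC-MS
intensities, an uncentered product is nearly collinear with the feature
column, which silently turns the "main effect" into the slope at CKD stage 0
and roughly halves power; centering restores the average-association
interpretation that a single per-cohort estimate implies. Replication: a
feature significant (α = 0.05) in discovery is re-fit in validation and
flagged replicated if significant there too. The pooled model drops the
interaction and adjusts for CKD stage, eGFR, age, weight and BMI; sex is
excluded by default (it is not significantly associated with blood pressure
in the reference cohorts), configurable. Benjamini–Hochberg adjustment is
applied to the replicated set's pooled p-values — applying it with m = 31 to
the bundled published table reproduces that table's printed adjusted column
to three significant figures, which is the one choice the published numbers
pin down. Headline selection: pooled raw p < 0.05; the stricter
BH-adjusted p < 0.05 set is flagged alongside.

Variance accounting uses adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) of
nested pooled models, covariates first, then features in pooled-p order. ROC
AUC is the midrank Mann–Whitney statistic U/(n₁n₀) against the binary
outcome; a feature with a negative association separates below 0.5, so the
acceptance summary reports the folded value 0.5 + |AUC − 0.5|.

## Neural-network importance

A fully connected classifier (scikit-learn `MLPClassifier`) predicts the
blood-pressure stage from standardized inputs; the outcome is one-hot
encoded over the stage classes. Defaults: two hidden layers (32, 16), ReLU,
softmax/cross-entropy, Adam at 1e-3, batch 32, 200 epochs, stratified 80/20
split, standardization statistics computed on the training split only. The
exact published architecture is not recoverable, so all of this is
configurable; non-convergence within the epoch budget is reported as-is.

Importance of a feature is its leave-one-feature-out ablation delta: the
model is *retrained* without the feature on the same split/seed schedule
(removal at training time, not input zeroing at test time) and the delta is
baseline minus ablated held-out accuracy — positive when removal hurts,
legitimately negative when removal helps. Single-run deltas on small
networks are noise-dominated, so deltas are averaged over a schedule of
seeds (default 10) and reported with their across-seed SD. Given a seed and
single-threaded training, the whole procedure is deterministic.

## Synthetic-data generator

The generator emulates the two-cohort study design so the pipeline can be
validated against known ground truth:

* **Cohorts.** Per-CKD-stage sample counts default to the published cohort
  summaries (discovery 144/125/133/131/150/141, validation 96/97/76/94/93/96,
  totalling 824 and 552). A second preset reflects the alternative counts
  printed in the same study's methods text; only the default sums to the
  stated totals. Covariates (age, eGFR, weight, BMI, sex) are truncated
  normals per stage with the published means/SDs, truncated at physiologic
  bounds (age 18–95 y, BMI 14–45 kg/m², eGFR > 1 mL/min/1.73 m², weight
  35–150 kg).
* **Features.** Default 200 features in 60 clusters (sizes as equal as
  possible; a geometric-size option exists). Each cluster is driven by one
  latent standard-normal factor; feature *f* in cluster *c* has latent value
  √ρ·g_c + √(1−ρ)·ε and intensity exp(μ_f + 0.5·z), log-normal as LC-MS
  intensities are. ρ is set by inverting the log-normal correlation formula
  so the expected pairwise |Pearson r| of the *intensities* equals
  `within_cluster_r` (default 0.7); the tests check the realized mean within
  ±0.1.
* **Outcome.** A latent score sums covariate contributions (slopes +0.08 per
  CKD stage, −0.005 per eGFR unit, +0.004 per year, +0.009 per kg, +0.032
  per BMI unit — the sign pattern of the published clinical model), the
  planted features' standardized latent values times their effect sizes
  (default 10 causal features, one per distinct cluster, 0.35 score units
  per SD), and N(0, 0.6) noise. The score is cut at within-cohort quantiles
  (stage proportions 0.25/0.15/0.25/0.30/0.05) into stages 1–5, and a
  (systolic, diastolic) pair is drawn uniformly inside that stage's band, so
  re-staging the readings reproduces the latent stage exactly — the coding
  operation is testable end-to-end. The default effect size comes from a
  desk power calculation: 0.35 SD on the latent score gives t ≈ 4–6 at the
  validation cohort's n after discretization and pivot attenuation, i.e. a
  regime where the replication design should succeed without being trivial.

What the generator does **not** model: missing values, batch effects,
heteroscedastic or non-Gaussian noise, correlation between covariates and
feature intensities (beyond what the outcome induces), adduct mass
relationships, or real metabolite identities. Passing recovery tests
therefore show the pipeline's logic and power under its own assumptions, not
performance on real serum data.

## Evaluation conventions

Because the reducer keeps one random pivot per cluster, recovery is scored
at cluster level: a planted feature counts as recovered if its cluster's
representative replicates, and a replicated representative whose cluster
contains no planted feature is a false discovery. Operating characteristics
are averaged over 10 generator seeds in the tests (sensitivity ≥ 0.8, FDP
≤ 0.2 at defaults; replication rate ≤ 1% with no planted effects).

The ablation and accuracy-curve analyses in the tests and the acceptance
script run on a reduced synthetic problem (60/40 samples per stratum, 30
independent features, one planted effect of 0.9 SD, hidden layers (16, 8),
150 epochs) — a size chosen so a full 10-batch ablation schedule remains a
desk-scale computation while leaving the planted-vs-noise contrast far above
the seed-to-seed noise floor.

## Known limitations

* The ordinal outcome is fit by OLS; estimates are interpretable as
  associations, not stage probabilities.
* The screening model centers the interaction; analyses that specifically
  target the slope at CKD stage 0 should fit their own contrast.
* BH is applied within the replicated set (m = number of replicated
  features), not across all screened features; this matches the published
  procedure it mirrors but is anti-conservative relative to screening-wide
  correction.
* `MLPClassifier` has no per-epoch validation curve or early stopping in the
  configuration used; accuracy is whatever the fixed budget reaches.
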