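# Methods

`neoscreen` models the two ways a newborn-screening laboratory can call a
dried-blood-spot MS/MS panel: the classical **cutoff scheme**, where each
analyte is compared against a nonparametric reference interval, and a
**risk-score scheme**, where per-disease classifiers produce a 0–100 score
thresholded by disease prevalence. Because real screening records are
protected health data, the package ships a synthetic cohort generator whose
disease structure matches a published 309,102-newborn regional program
(16 inherited metabolic diseases, overall incidence ≈ 1:2,034, carriers
slightly outnumbering affected among confirmed positives at 80:72).

## Synthetic cohorts

Each subject is independently assigned a disease status: per disease,
affected with probability `prevalence`, carrier with probability
`carrier_multiplier × prevalence` (default 80/72 ≈ 1.11), else unaffected.
Prevalences default to the published per-disease case counts over 309,102.
An `enrichment` factor multiplies all prevalences to produce case-rich
training cohorts.

**Healthy analytes** are log-normal, parameterized by a median and a
log-scale sd per analyte (43 analytes: 11 amino acids, 31 acylcarnitines,
succinylacetone; all μmol/L). Published sources do not print healthy
reference statistics, so the baseline table is synthetic: medians sit at
typical newborn DBS values and the spreads were chosen so that the published
borderline cases fall on the correct side of the simulated 0.5–99.5%
interval (e.g. PHE 78.66 inside / 103.02 outside; C5OH 0.48 inside / 0.53
outside; MET 51.7 outside; C0 9.79 inside the lower bound).

**Disease-class marker analytes** are drawn from marginals that reproduce the
published per-class mean ± SD *exactly* on the non-negative axis:

* a zero-truncated normal whose parent (μ, σ) is solved from the truncated-
  normal moment identities so the post-truncation mean and SD equal the
  configured values. Naively truncating N(mean, sd) would inflate the
  realized mean whenever the class has appreciable mass below zero
  (3-MCCD affected, 4.35 ± 4.44, has ≈16%), which would make simulated
  moments disagree with the configured ones;
* a moment-matched log-normal when `mean/sd < 1.2`, because a
  zero-truncated normal cannot realize a coefficient of variation at or
  above 1 (affects PAHD carrier, PCD carrier, and both 3-MCCD classes).

Classes observed only once in the source program carry a synthetic sd of 25%
of the printed value; classes never observed (e.g. an affected case of a
disease seen only in carriers) carry synthetic means placed between the
observed class and the healthy baseline. All such entries are marked in
`data/diseases.yaml`.

Covariates (gestational age 39 ± 1.5 weeks clipped to [24, 44], birth weight
3,300 ± 450 g, collection interval ≈ 4 days, sex, feeding) are sampled
independently of the analytes; hooks for covariate–analyte trends exist but
default to none, since no effect sizes are published. One disease per
subject; co-occurrence is not modeled.

What the generator does *not* emulate: laboratory batch/QC structure,
instrument drift, analyte–analyte correlation in healthy subjects,
within-disease genotype heterogeneity (a single pooled mean ± SD per class),
and covariate effects on metabolite levels. Passing tests therefore show
that the pipeline's statistical machinery behaves as specified under the
configured study conditions, not that it would achieve the same rates on
real screening data.

## Cutoff scheme

Reference intervals use the standard nonparametric rank convention: for
percentile p on n sorted values, rank `r = p/100·(n+1)`, linearly
interpolated and clamped to [1, n]; defaults 0.5 and 99.5. Intervals built
from fewer than 120 values are flagged unreliable. Flagging is
direction-aware: a disease is flagged only when a marker analyte violates
the interval on the disease's deviation side — raised markers on the high
side, lowered markers (low free carnitine in PCD, low citrulline in OTCD) on
the low side. A record is screen-positive when any disease is flagged.

The two-tier workflow recalls every initial positive and simulates a second
specimen as a Gaussian-copula re-draw of the panel at test–retest
correlation 0.8 (configurable; 1.0 reproduces the first panel exactly, 0.0
is an independent specimen). A recalled subject whose re-drawn panel still
flags is "suspected" — the pool that would be referred for confirmatory
sequencing.

With 16 diseases flagging on ~17 one-sided 0.5% marker tests, the union
initial positive rate of the simulated cutoff branch is ≈8%, higher than a
real program's (published: 1.17%); real cutoffs are wider than the
population percentiles and analytes are correlated. The cutoff-vs-risk-score
comparison is therefore treated as directional, not absolute.

## Features and selection

MoM(a) = concentration(a) / median(a), with medians computed per cohort by
default (external medians supported for multi-laboratory harmonization).
Feature vectors are the 43 analyte MoMs plus gestational age, collection
interval and birth weight (46 features, fixed order). Features are ranked by
information gain — mutual information in bits between the decile-binned
feature and the binary disease label — and filtered for redundancy by
Pearson correlation on the discretized scale (defaults: IG ≥ 0.001 bits,
|r| ≤ 0.95). IG is computed on MoM values, the quantity the models consume.

## Risk models

One-vs-rest binary classifiers per disease, with carriers counted as
positives (the program's confirmed-positive set includes carriers). The
algorithm registry ships nine classical families (logistic regression, LDA,
decision tree, random forest, extremely randomized trees, gradient boosting
via histogram GBDT, AdaBoost, SVM, k-NN); any `factory(seed) -> estimator`
with `predict_proba` can be registered. The end-to-end pipeline defaults to
the three fast families (logistic regression, random forest, gradient
boosting) so a full run completes in well under a minute on one CPU.

Training protocol: an 8:2 stratified split of a case-enriched training
cohort (defaults: n = 30,000 at 60× prevalence — a stand-in for the large
multi-site case-rich corpora production models are trained on). Candidates
are fitted on the 80% side; on the 20% side each candidate's operating
threshold is set to the largest raw score that still captures every
validation positive (zero false negatives), and the candidate with the
fewest false positives wins (ties by algorithm id). If no candidate reaches
zero FN, selection falls back to maximum sensitivity with a warning.

Raw scores map to 0–100 through the linearly interpolated empirical CDF of
held-out healthy scores (≥1,000 recommended; scores below/above all healthy
scores map to 0/100). This mapping is a monotone, bounded, prevalence-
calibratable stand-in for an unpublished proprietary mapping, not a
reconstruction of it. The high-risk threshold per disease is the smallest
score whose healthy exceedance is at most `recall_multiplier × prevalence`
(default multiplier 5), so the expected healthy flag rate tracks disease
prevalence; for very rare diseases with small calibration sets this
degenerates to "flag only at the score ceiling", which is the conservative
limit.

## Evaluation

Confusion counts against genetically confirmed status (affected or carrier =
positive), with sensitivity, specificity, PPV, NPV and accuracy computed at
full precision and rounded half-up to 2 decimals only for presentation.
Undefined metrics (zero denominator) are reported as not-available, never as
0. Per-disease false-negative rates, zygosity-stratified true-positive
rates, screening positive rates and `1:N` incidence ratios follow the same
conventions. The packaged `study_counts.json` holds only the published
*integer counts*; every percentage is recomputed from them at run time.

## Numerical choices

* Truncated-normal parent parameters: Brent root-finding on the standardized
  truncation point in [-12, 12], hazard evaluated in log space; classes with
  mean/sd > 12 use the parent parameters unchanged (truncation mass < 1e-33).
* Degenerate classes (sd = 0) are point masses; the copula re-draw gives
  them a zero normal score.
* Copula CDF values are clipped to [1e-12, 1 − 1e-12] before the normal
  quantile transform.
* Feature-selection and model-selection ties break lexicographically; the
  split shuffles within strata with a seeded generator; all randomness fans
  out from a single master seed through `numpy.random.SeedSequence`.
* Risk-score thresholds scan distinct calibration scores ascending and take
  the first whose tail count is within budget (monotone in the recall
  multiplier by construction).

## Problem sizes

Default pipeline scale: 50,000 screened subjects, 30,000 training subjects
at 60× enrichment, three algorithm families, 16 diseases — chosen so the
rarest diseases still contribute a handful of training positives while a
complete simulate–train–assess–evaluate cycle stays interactive (≈30 s).
Diseases with fewer than 2 training positives are skipped with a warning
rather than fitted degenerately.

## Known limitations

* Absolute positive rates of the simulated cutoff branch exceed a real
  program's (see above); comparisons between branches are directional.
* Single pooled mean ± SD per disease-zygosity class; no mild/classic
  phenotype substructure.
* Secondary-screen metabolite *ratios* (e.g. PHE/TYR) are not enumerated in
  any published source available here and are off by default.
* The risk-score mapping and the carrier-prevalence multiplier are
  principled stand-ins for unpublished components, exposed in configuration.
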