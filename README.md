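# neoscreen

Simulation and evaluation of neonatal screening for inherited metabolic
diseases (IMDs), comparing the classical **cutoff scheme** — per-analyte
nonparametric reference intervals on a tandem-MS amino-acid/acylcarnitine
panel — against a **machine-learning risk-score scheme** with per-disease
classifiers, 0–100 risk mapping and prevalence-guided thresholds.

It is written for screening laboratories, biostatisticians and methods
researchers who want to study the trade-offs of the two schemes (recall
burden, false positives, carrier detection) without access to protected
screening records: a seeded synthetic cohort generator reproduces the
disease structure of a published 309,102-newborn regional program — 16 IMDs,
overall incidence ≈ 1:2,034, 72 affected (homozygous/compound heterozygous)
vs 80 heterozygous carriers among confirmed positives, and per-class marker
distributions such as PHE 966.45 ± 618.33 μmol/L for affected
phenylalanine-hydroxylase deficiency (PAHD) versus 270.15 ± 256.90 μmol/L
for carriers.

## The two schemes

**Cutoff:** for each analyte a reference interval `[Q_0.5%, Q_99.5%]` is
estimated by the nonparametric rank convention (rank `r = p/100·(n+1)`,
linear interpolation). A disease is flagged when a marker analyte violates
the interval on the disease's deviation side (PHE high for PAHD, free
carnitine C0 low for primary carnitine deficiency, …). Initial positives
are recalled; a correlated re-test decides who stays "suspected".

**Risk score:** per disease, a one-vs-rest classifier over multiple-of-median
(MoM) features `x_a / median(x_a)` plus gestational age, collection interval
and birth weight. Candidate algorithms are selected by a zero-false-negative
rule (keep candidates that catch every validation positive, pick the one
with fewest false positives). Raw scores map to 0–100 through the empirical
CDF of healthy calibration scores, and the high-risk threshold per disease
is set so the healthy flag rate is at most `recall_multiplier × prevalence`.

**Evaluation:** sensitivity, specificity, PPV, NPV and accuracy from the 2×2
confusion table against confirmed status (carriers count as positives),
per-disease false-negative rates, zygosity-stratified true-positive rates,
positive rates and `1:N` incidence ratios.

See `docs/methods.md` for the full model description and its limitations.

## Worked example

Push the published confusion counts of the ML scheme (142 TP, 6 FP, 22 TN,
10 FN among 180 sequenced suspected cases) through the evaluator:

```python
>>> from neoscreen import ConfusionCounts, diagnostic_metrics, incidence_ratio
>>> diagnostic_metrics(ConfusionCounts(tp=142, fp=6, tn=22, fn=10)).rounded().as_dict()
{'sensitivity': 93.42, 'specificity': 78.57, 'ppv': 95.95, 'npv': 68.75, 'accuracy': 91.11}
>>> incidence_ratio(152, 309102)
'1:2,034'
```

i.e. the scheme caught 93.42% of confirmed cases, 78.57% of the
non-diseased suspected cases were correctly cleared, and one newborn in
2,034 carried a confirmed IMD.

Run the full synthetic pipeline (simulate → intervals → cutoff screen →
features → train → assess → evaluate) from the shell:

```bash
neoscreen run-all --seed 7 --cohort-size 20000 --out demo_run
```

`demo_run/report.json` then contains, among other blocks:

```json
"positive_rate": {"ml_system": 0.64, "reference_interval": 8.195},
"n_suspected": 629,
"suspected_metrics": {
  "ml_system": {"tp": 11, "fp": 74, "tn": 543, "fn": 1,
                "sensitivity": 91.67, "specificity": 88.01, ...}
}
```

reading: the risk-score branch flagged 0.64% of the 20,000 simulated
newborns initially versus 8.195% for the cutoff branch, and among the 629
suspected cases it kept high sensitivity while being far more specific than
the cutoff branch (which, by construction, flags every suspected case).
Every stage is also available as its own subcommand (`neoscreen simulate`,
`intervals`, `screen`, `features`, `train`, `assess`) and as library
functions.

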