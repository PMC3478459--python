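# generisk

Gene-expression-based prognostic risk scores for right-censored survival
cohorts.

Bulk expression profiling of a cancer cohort (the motivating setting is
cytogenetically normal acute myeloid leukemia, where no karyotype
aberration guides risk assignment) routinely asks: which probes carry
prognostic information, how should they be combined into a single
per-patient risk score, and does that score transfer to an independent
cohort measured on a different platform?  `generisk` implements that whole
chain as a tested library:

- **Probe screening** by maximally selected rank statistics: for probe *i*
  with expression *e_ij*, every candidate cutpoint *μ* inside the 10–90%
  quantile window defines a dichotomy *e_ij > μ*, scored by the
  standardized log-rank statistic *z(μ) = (O − E)/√V*; the probe's
  statistic is *M_i = max_μ |z(μ)|* with the Lausen–Schumacher
  approximation correcting the p-value for the maximization, and
  Benjamini–Hochberg controlling the FDR across probes.
- **Risk score**: each selected probe gets a univariate Cox coefficient
  *β_i* for its dichotomy at the selected cutpoint *c_i*; a patient's score
  is *S_j = Σ_i s_ij β_i* with *s_ij = +1* if *e_ij > c_i*, else −1.
- **Thresholding**: the high/low cut *τ* maximizes the absolute
  standardized log-rank statistic between *{S ≤ τ}* and *{S > τ}* over all
  observed score values.
- **Frozen-model transfer**: an independent cohort is scored with the
  training cutpoints and betas, and split either at *τ* (`by_value`) or at
  the training high-risk proportion (`by_proportion`, the default — immune
  to affine cross-platform signal shifts).
- **Single-gene stratification**: an independently prognostic gene
  (EVI1-like), dichotomized at its own survival-optimal cutpoint, refines
  the score-high group into a three-group partition with distinct survival.
- **Synthetic cohorts**: a generator producing expression + survival data
  with planted prognostic structure, so every stage is testable without any
  external download.

Supporting machinery (Kaplan–Meier curves with a "not reached" median
sentinel, k-sample log-rank tests, uni/multivariate Cox fits, group-wise
rank-sum score comparisons) is exposed under `generisk.survival`.

## Worked example

`examples/03_risk_score_transfer.py` simulates a 163-patient training and
79-patient validation cohort on a shared synthetic platform, screens 1000
probes, builds the score and transfers the frozen model:

```
model: 27 probes, tau = 11.68, training high-risk proportion = 24.5%
validation: high-risk fraction 24.1%, log-rank p = 2.08e-06, median OS (months) = {'high': '2.5', 'low': '13.0'}
after platform distortion: by_proportion flags 24.1% high risk (target 24.5%); by_value flags 100.0%
```

Reading: 27 probes survive the FDR-controlled screen (25 planted signature
probes plus 2 false positives — see `examples/02_probe_selection.py`); the
score threshold found on the training cohort carries over to 79 new
patients, whose predicted high-risk quarter dies with a 2.5-month median
OS versus 13 months for the rest (log-rank p ≈ 2×10⁻⁶).  After an affine
distortion of the validation platform's measured signal, proportion-based
transfer still flags the intended fraction of patients, while raw-value
thresholding collapses (everyone looks high-risk).

`examples/04_gene_stratification.py` adds the single-gene layer:

```
EVI1-like dichotomy: cutpoint 6.02, univariate HR 1.83
  low_risk: n=89 (55%), median OS 21.3 months
  high_risk_gene_low: n=38 (23%), median OS 3.4 months
  high_risk_gene_high: n=36 (22%), median OS 1.9 months
3-group log-rank: chi2 = 118.1 (df=2), p = 2.28e-26
```

## Command line

The same pipeline runs from a shell:

```bash
generisk simulate --out-prefix demo --seed 7
generisk train --expression demo_training_expression.tsv \
               --clinical demo_training_clinical.tsv --model-out model.json
generisk apply --model model.json --expression demo_validation_expression.tsv \
               --clinical demo_validation_clinical.tsv --scores-out scores.tsv
generisk run-all --simulate --seed 7 --output-dir run/
```

`run-all` writes the selection table, Cox table, per-patient scores, KM
curves, stratification tables, a score-ordered expression heatmap and a
machine-readable manifest.

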