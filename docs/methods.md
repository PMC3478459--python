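# Methods

## The model

Patients carry right-censored overall-survival times (months) and a
probes × patients matrix of already-normalized, log-scale expression
values.  The analysis treats every probe as a candidate *dichotomous*
prognostic marker: a cutpoint *c* splits the cohort into
high (*e > c*, strictly) and low (*e ≤ c*) groups, and prognostic value is
the two-sample log-rank contrast between them.  No normalization,
probe-set summarization or array QC is performed here; the input is
assumed to be the output of such a pipeline.

### Maximally selected log-rank statistics

For a probe, candidate cutpoints are the distinct observed values whose
empirical quantile (fraction of observations ≤ the value) lies in
[q_low, q_high], default [0.10, 0.90].  The window keeps both groups away
from degenerate sizes and bounds the variance of the standardized process.
Each candidate is scored with the standardized log-rank statistic
accumulated over distinct event times with the hypergeometric variance at
ties; the probe's statistic is the maximal absolute value, ties broken
toward the smallest cutpoint for determinism.

Because the maximum over many correlated statistics is not standard
normal, p-values use the Brownian-bridge crossing approximation of Lausen
and Schumacher (1992):

    p(m) ≈ φ(m)(m − 1/m)·log[ q_high(1−q_low) / (q_low(1−q_high)) ] + 4φ(m)/m.

This expansion is accurate for moderately large m but degenerates (even
turning negative) for small m, so the implementation floors it at the
pointwise two-sided tail 2(1−Φ(m)) — a valid lower bound, since the
supremum dominates any single statistic — and caps it at 1.  The
approximation is mildly conservative at cohort sizes near 163: in the
package's null simulation the empirical type-I rate at nominal 0.05 is
≈ 0.045.  Across probes, Benjamini–Hochberg step-up adjustment controls
the FDR; selection uses strict inequality (adjusted p < α, default
α = 0.05).

A corollary worth knowing: the hazard ratio re-fitted at the *selected*
cutpoint inherits the selection bias of the maximization and
overestimates the marginal effect (in the default simulation, true
marginal HR 3 probes refit around 4–5 at n = 163).  The package reports
these fitted values because they are what the downstream score uses, but
effect-size recovery in the test-suite is assessed at the planted
cutpoints, where the estimate is unbiased.

### Score, threshold, transfer

Each selected probe receives a univariate Cox coefficient β for its
dichotomy (Efron ties, maximum partial likelihood); monotone-likelihood
probes (all events on one side) are flagged and capped at |β| = 10 rather
than diverging.  The patient score is the ±β sum; by construction it lies
in [−Σ|β|, +Σ|β|], attained by the all-below / all-above patients, and
equality with a cutpoint counts as "below" (consistent with the
strict-greater high side).

The score threshold τ scans every distinct observed score (excluding the
maximum, which would empty the high group), maximizing the absolute
standardized log-rank statistic; exact ties prefer the more balanced
split, then the smaller τ.  τ may equal the minimal achievable score in
degenerate models (e.g. a single probe), hence the half-open containment
[−Σ|β|, +Σ|β|).

Transfer to an independent cohort freezes (c_i, β_i, τ, p_high) — nothing
is refitted.  Two modes:

- `by_value`: high iff S > τ.  Appropriate when both cohorts are on the
  same platform and scale.
- `by_proportion` (default): the top round-half-up(p_high·n) scorers are
  high, where p_high is the training fraction above τ.  Because the ±β sum
  is invariant to monotone per-probe transformations only through the
  cutpoints, an affine platform shift moves essentially every patient to
  one side of the frozen cutpoints and destroys by-value classification;
  ranking by score within the new cohort is far more robust.  The
  generator's distortion option reproduces exactly this contrast.

### Survival machinery

Kaplan–Meier estimation and Cox fits are delegated to lifelines.  The
median convention is the smallest observed time with S(t) ≤ 0.5, and "not
reached" is propagated as an explicit sentinel (`None` in memory, the
string `not reached` in reports) — never as a number.  The k-group
log-rank test is lifelines' multivariate test; for k = 2 its chi-square
equals the square of the package's own standardized statistic, which the
tests use as a cross-check between the two code paths.  Cox tie handling
defaults to Efron; a compact in-package Newton–Raphson fit of the Breslow
partial likelihood is provided for cross-checking against software that
uses Breslow, and coincides with the Efron fit on tie-free data.
Group-wise score comparisons (e.g. across FAB-like subtypes) are two-sided
Mann–Whitney tests of each group against all remaining patients; groups
with fewer than 3 members are reported descriptively without a p-value.

### Three-group stratification

A single prognostic gene is dichotomized at its own maximally selected
cutpoint.  The headline partition keeps score-low patients together
regardless of gene status (G1) and splits score-high patients by the gene
(G2 low, G3 high); the four-way score × gene table is also computed, the
three-group view being its documented merge of the two score-low cells.
Merging G2 and G3 reproduces the two-group high-risk KM curve exactly
(tested).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
~10³ probes of Gaussian log-intensities (per-probe means uniform on
[4, 12], sds on [0.6, 1.4]), exponential survival, administrative
censoring at a 60-month follow-up horizon, optional independent
exponential censoring, optional FAB-like subtype labels, and an optional
independent single prognostic gene (default log-HR 0.7, cutpoint at its
60th percentile).  Defaults: 163 training patients, 79 validation
patients, 1000 probes (a desk-scale stand-in for a ~44k-feature array),
25 planted prognostic probes with β_true = 1.1 (per-probe dichotomized
HR ≈ 3), baseline hazard ln 2 / 12 per month.

Two generative modes:

- **latent** (default): patients carry a latent risk axis u ~ N(0,1);
  planted probes are noisy readouts of u with loading a = 0.85, and the
  log hazard is γ·u with γ = mean(β_true).  This mirrors how a real
  prognostic signature behaves — co-expressed probes tracking one
  underlying biological axis — and is calibrated so the *marginal*
  dichotomized hazard ratio of each planted probe is ≈ exp(β_true): the
  median split recovers a 2φ(0)·a ≈ 1.36 sd shift on u, and residual
  frailty plus censoring attenuate the Cox coefficient by ≈ 0.74, the
  product returning ≈ 1.0·β_true (verified by simulation at n = 30 000).
  Under these conditions the screen recovers the planted signature
  essentially completely at n = 163, and the aggregated score carries a
  two-group Cox HR of ≈ 5–7.
- **independent**: probes are mutually independent and the log hazard is
  the literal sum Σ β_true·1{e > c} over planted probes.  With a single
  planted probe the marginal HR converges to exp(β_true) (tested at
  n = 5000); with many planted probes the other probes act as unmodelled
  frailty (log-hazard sd ≈ 2.7 at 25 × β = 1.1), attenuating every
  *marginal* per-probe HR to ≈ 1.4 and making the signature essentially
  unrecoverable at n = 163.  This mode therefore serves single-probe
  calibration, closed-form checks and robustness experiments; it is not a
  model of a recoverable signature, which is why it is not the default.

What the generator does **not** model: probe-level microarray noise,
batch effects beyond a global affine distortion, correlation among null
probes, subtype labels coupled to risk, or non-proportional hazards.
Passing tests therefore demonstrate correctness of the statistical
machinery under a clean proportional-hazards regime, not robustness to
array artifacts or model misspecification on real data.

Ground truth (planted probe identities, cutpoints, betas, the latent
axis) travels on a separate channel from the dataset and is never read by
any analysis stage (tested by deleting it and re-running).

## Numerical and design choices

- Candidate cutpoints and score thresholds are observed data values;
  all tie-breaks are deterministic (smallest cutpoint; most balanced then
  smallest threshold), so every fit is reproducible bit-for-bit given a
  seed.
- The vectorized scan is required to agree with an exhaustive brute-force
  dichotomy search bit-for-bit on the argmax and to 1e-10 on the
  statistic (tested on 200 random probes at n = 163).
- Probes without an admissible cutpoint (constant values, empty window)
  are skipped with a warning during screening, not fatal.
- Expression readers reject non-finite values outright; clinical readers
  drop non-positive follow-up times with a logged count and reject event
  indicators outside {0, 1}.  Decimal-comma tables are supported via a
  `decimal` option.
- Identifier joins are case-sensitive exact matches; cohort alignment
  restricts both components to the identifier intersection in the
  expression matrix's column order, making it idempotent.
- The selection-table writer prints HRs to 2 decimals and p-values to 4
  (conventional reporting precision) while keeping cutpoints and betas at
  full precision, so a written model round-trips losslessly.
- Problem sizes in the test suite (163/79 patients, 1000 probes, 100–1000
  replicate simulations) match the package's default study conditions and
  keep the full suite under a minute.

## Known limitations

- The maxstat p-value is an asymptotic approximation; no exact or
  permutation-based null is provided.
- The score admits only ±1 weights; continuous or penalized weighting is
  out of scope.
- No competing risks, time-varying covariates or proportionality
  diagnostics.
- `by_proportion` transfer assumes the validation cohort is drawn from a
  comparable case mix; if the true high-risk prevalence differs between
  cohorts, fixing the proportion misclassifies by construction.
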