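# Methods

This note documents the statistical procedure implemented in `gepsig`,
the choices made where the published workflow leaves details open, what
the synthetic benchmark does and does not emulate, and the numerical
conventions the tests rely on.

## The discovery procedure

### Normalization

`median_scale` shifts every sample column additively so its median
equals the grand median of the matrix; `batch_center` shifts every
(probe, batch) cell block so the batch mean equals the probe's grand
mean. Both are additive per group, preserve within-sample (resp.
within-batch) contrasts exactly, and are idempotent to machine
precision. For prospective application both accept frozen references
(the training grand median; per-probe training means), so a validation
cohort is normalized *onto* the training scale without its outcomes
influencing anything — the only leakage-free reading of a
train-then-validate design. No empirical-Bayes batch correction is
attempted; the model is purely additive.

### Probe filtering

The variability filter keeps probes with raw median absolute deviation
(no 1.4826 consistency factor) at or above 0.5 on the log2 scale —
the unscaled statistic matches how MAD filters are conventionally
thresholded in microarray suites. The redundancy filter z-scores probe
rows, runs k-means (k = max(2, n/10), 10 restarts, fixed seed) and
retains a probe only when Pearson correlation between its profile and
its assigned centroid is ≥ the correlation radius (default 0.95).
Singleton clusters trivially retain their probe. The retention rule is
an interpretation of "failed to cluster with this stringency": probes
that are not tightly representative of any co-expression cluster are
eliminated. Consequences worth knowing: at radius 0.95 a surviving
probe is necessarily either near-duplicate of a tight co-expression
group or isolated in its own cluster, so the filter is aggressive on
diffuse data; retention is monotone in the radius for a fixed
clustering.

### Censoring-aware response

With ~86% censoring, class labels or raw times are poor regression
targets. The package uses null-model (covariate-free) deviance
residuals: Λ̂ is Nelson–Aalen, `m_i = δ_i − Λ̂(t_i)`,
`d_i = sign(m_i)·sqrt(−2[m_i + δ_i ln(δ_i − m_i)])` with the δ=0 log
term taken as 0. The null model is used because residuals are computed
before any fitted model exists. The residual vector is scaled to unit
mean square (`‖y‖₂ = √n`, the "Euclidean-length-equivalent" scale),
which makes the SVR's ε and C scale-free. The residuals serve as the
*dependent* variable throughout (both for the SVR and for the
partition cutoff); treating them as predictors instead would leave the
workflow without a response.

### Support-vector regression

ε-insensitive SVR with an RBF kernel on per-probe z-scored features
(training statistics frozen into the model). Defaults: C = 1, ε = 0.1,
and bandwidth `gamma = 1/(30·p)` ("smooth"). The conventional
`gamma = 1/(p·var)` makes the kernel local enough to interpolate the
training cohort: the training concordance then saturates near 1 for
arbitrary probe subsets, and predictions for samples outside the
training cloud collapse to the intercept, which destroys both model
selection and frozen validation. The wide default keeps the regression
near-linear, trading training fit for out-of-cohort transfer; `"scale"`
remains available.

### Subset search

A genetic algorithm over bit masks: subset size clamped to [15, 21]
(centered on the 18-probe target), tournament selection (size 3),
uniform crossover (p = 0.8), per-bit mutation (1/n), elitism 1,
population 100 × 50 generations by default. Candidate fitness is the
lexicographic tuple (max Harrell C, min AIC, min BIC, min RMSE), with C
and RMSE computed **out-of-fold**: predictions are assembled from two
deterministic 3-fold splits (seeded from the GA seed) and averaged.
In-sample fitness is not usable here — see the SVR note above. AIC/BIC
are Gaussian-likelihood surrogates on the out-of-fold residuals with
parameter count |subset|+1; with a continuous concordance they act only
as tie-breakers. The initial population is warm-started from the
univariate Spearman ranking of probes against the response (including
deterministic top-k individuals), a standard screening device that
spends the limited evaluation budget refining rather than locating
signal; the search may discard screened probes freely. The whole
search is bit-reproducible from its seed.

At the emulated sample size (127 samples, ~18 events) the out-of-fold
concordance of a candidate subset carries a standard error of several
points; selection over a thousand candidates therefore overfits the
criterion by a comparable margin (winner's curse). Exact probe-identity
recovery is only achievable when the filtered candidate pool is small
and signal-dominated; this drives the synthetic benchmark's design
(below) and is the main caveat for applying the pipeline to diffuse
real data.

### Scores, transform, cutoff, classes

Raw SVR predictions are standardized by the training-prediction
mean/SD and logistic-squashed to (0,1) — a rank-preserving analogue of
a probability output. Scores are then rank-based inverse-normal
transformed (Blom offsets `(r − 3/8)/(n + 1/4)`), affinely rescaled to
[0,1]; ties share values. Because classification is invariant under any
strictly monotone transform applied jointly to scores and cutoff, this
choice compresses outliers without being able to change classes. The
cutoff is the single CART regression split of the residuals along the
transformed-score axis (midpoint of the adjacent distinct pair
maximizing the between-group sum-of-squares reduction; ties toward the
smaller cutoff), with a minimum leaf of max(5, 10% of the cohort) in
the discovery pipeline — without it the optimal split tends to isolate
a handful of extreme residuals and yields a powerless risk class.
Scores at or below the cutoff are *Favorable*; above it,
*Non-favorable*. The training (raw → transformed) pairs are stored in
the model artifact and applied to new cohorts by monotone
interpolation, so validation never re-ranks within itself.

### Cross-validation

"50-fold cross-validation with 10% holdout" cannot be a disjoint
partition; it is implemented as 50 independent random 90/10 splits,
refitting the SVR each time and averaging holdout RMSE. The reported
RMSE is on the standardized-response scale.

### Evaluation

Misclassification among events is the fraction of recurrences
classified Favorable (every recurrence belongs in Non-favorable by
convention). Kaplan–Meier medians report the smallest time with
Ŝ(t) ≤ 0.5 and an explicit undefined marker when the curve never
reaches 0.5. The log-rank test and KM curves come from lifelines. The
Cox model is a Newton–Raphson maximizer of the Breslow partial
likelihood written for this package: it exposes the convergence flag
and monotone-likelihood (separation / empty-stratum) detection the
report format needs, with step-halving to keep the likelihood ascent
monotone; it is cross-checked against lifelines in the test suite.
Categorical covariates are expanded against fixed reference levels
(WHO I, mitotic ≤2, Simpson 1, female, non-skull-base); multivariate
fits drop samples with missing covariates listwise and log the count;
non-estimable strata are flagged per row rather than aborting the
report.

## The synthetic benchmark

`SimConfig` defaults generate what the pipeline assumes: a 127-sample
training and 62-sample validation cohort, 2000 probes on a log2-like
scale (location 7.0), three tiers of probes —

- 18 **signature probes** in 3 co-expressed "programs" of 6 (latent
  factor, within-program correlation 0.95), per-probe SD ~ U(0.9, 1.3);
- 600 probes in 20 background **co-expression blocks** of 30 with
  within-block correlation ~ U(0.74, 0.87) and lognormal SDs centered
  near 1.0;
- independent **noise probes** with lognormal SDs centered near 0.33;

additive per-(probe, batch) offsets (SD 0.3; 3 training batches, 1
validation batch); event times `t ~ Exponential(λ0·e^η)` with
λ0 = 0.06/year and `η = Σ β_g z_g` over the planted probes' z-scored
expression (β = ±0.3, signs alternating by program); censoring =
min(uniform dropout, 25.42-year administrative window) with the dropout
scale solved numerically so the expected censoring fraction hits the
cohort target (85.83% train / 80.65% validation); a WHO-grade-like
covariate correlated with η (so multivariate adjustment is exercised)
plus unrelated mitotic/Simpson/sex/location columns. All draws are
reproducible from a single seed; a cohort with zero events is redrawn
with a warning.

Design rationale, recorded as the package's own choices:

- **Programs, not independent probes.** Tightly co-expressed programs
  are how prognostic genes appear in tumors, and they are the only
  structure that both survives a 0.95 correlation radius and leaves
  each planted probe enough marginal signal (≈1/3 of η rather than
  1/18) to be identifiable at 18 events. Independent planted probes
  are available via `signature_group_size=1`, but subset recovery is
  then not statistically identifiable at this design's event count.
- **Pool concentration.** Background block correlations are drawn just
  below the radius threshold, so the redundancy filter reduces ~430
  MAD-passing probes to a candidate pool of ~20–35 dominated by the
  signature programs. This mirrors the intent of aggressive upstream
  filtering and is what makes probe-identity recovery (Jaccard ≥ 0.4)
  robust to the GA's selection noise.
- **Effect size.** β = 0.3/probe puts the *discovered* model's
  validation concordance around 0.85–0.95 across seeds — the
  "feasible" side of hard-but-feasible; weaker signal leaves recovery
  dominated by winner's-curse noise at n = 127.
- **Marginal indistinguishability.** Signal is survival-linked only;
  planted probes' means and SDs match ordinary high-variability
  probes, so no marginal statistic reveals them.

What the generator does **not** emulate: probe-level microarray
artifacts (background, cross-hybridization, platform mapping),
non-proportional hazards, tiered hazards across WHO grades, and
real-data co-expression that is diffuse rather than block-structured.
Passing recovery tests on this benchmark therefore demonstrates that
the pipeline's plumbing and statistics behave as designed under its own
assumptions — not that an 18-probe signature is recoverable from any
127-sample microarray cohort.

## Numerical conventions

- Event ties in the Cox fit: Breslow. Simulated times are continuous
  (floored at 0.005 years only to keep them positive), so the
  difference from Efron is negligible in tests.
- Harrell C: a pair is comparable iff the shorter time is an event;
  equal-time pairs are excluded; tied scores on comparable pairs count
  0.5.
- Per-stage seeds derive from the top-level seed via
  `SeedSequence([seed, stage_id])`, so stages are independently
  reproducible and artifacts are byte-identical across reruns (the run
  manifest stores the config hash and seed, and deliberately no
  timestamps).
- Degenerate inputs fail loudly and early: empty matrices,
  zero-variance probes entering the redundancy filter (named in the
  error), all-censored outcomes, constant residuals at the partition
  step, infeasible censoring targets (with a diagnostic), and
  validation matrices missing model probes (listed).

## Known limitations

- The GA's out-of-fold criterion remains noisy at ~18 events; on
  diffuse pools of hundreds of candidates, subset identity should be
  treated as unstable even when risk discrimination validates well.
- AIC/BIC for an SVR are surrogates, not likelihood-exact quantities;
  they matter only for exact concordance ties.
- The rank-based score transform is frozen by interpolation; scores
  outside the training range clamp to the endpoints (classification is
  unaffected unless the cutoff sits at an extreme).
- No competing risks, time-dependent covariates, interval censoring,
  or stratified Cox models.
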