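# Methods

`poolscreen` implements and evaluates pooled-sample ("group testing")
designs for screening many antibody–disease associations in case-control
studies, where assaying every individual against every antigen is the
dominant cost.

## Statistical model and procedures

### Pooled prevalence estimation

Within each study arm, individuals are partitioned at random into disjoint
pools of exactly `k` members; a pool is truly positive for an antibody when
any member is positive.  With `x` positive pools out of `n`, the
individual-level prevalence is estimated by the bias-corrected (Burrows)
estimator

    p̂ = 1 − (1 − x/(n+v))^(1/k),   v = (k−1)/(2k),

which removes most of the bias of the pooled MLE `1 − (1 − x/n)^(1/k)` and
has smaller mean-square error for prevalences up to 0.5.  Its variance is
computed from the published expression in θ = (1−p̂)^k; the subtracted
second term is a squared bracket of order 1/n⁴ and numerically negligible,
and any negative evaluation is clamped to zero.  At `x = 0` both the
estimate and the variance are exactly zero; `p̂ = 1` arises only in the
degenerate un-pooled case `k = 1, x = n`, where the variance is taken as 0.
A caveat for users needing exact agreement with other software: the
subtracted term of the printed variance expression circulates in slightly
different typographic forms, so implementations should be cross-checked
against the original group-testing literature; operationally the term is
irrelevant at realistic `n`.

### Two-phase screening

Phase 1 compares the case and control Burrows estimates per antibody with a
two-sided z-test, `z = (p̂_case − p̂_control)/√(var_case + var_control)`.
Antibodies with p-value below a user-chosen cutoff `c₁` (default 0.3)
advance; the rest are declared non-significant with no further assays.  When
neither arm has a positive pool the comparison is defined as non-significant
(`z = 0, p = 1`).

Phase 2 retests, individually, every member of an observed-positive pool of
an advancing antibody (members of negative pools are imputed negative
without assays), builds the reconstructed 2×2 case/control table, and
applies a two-sided Fisher exact test under the point-probability
("minlike") convention.  The antibody is significant when this p-value falls
below a prevalence-dependent cutoff `c₂`.

### Calibration of the phase-2 cutoff

Because rejection requires clearing both hurdles, `c₂` must be calibrated so
the overall per-antibody type-I error equals the nominal α.  For each
prevalence on a 0.00–1.00 grid in steps of 0.01, many null antibodies (both
arms i.i.d. Bernoulli at that prevalence) are pushed through the full
two-phase procedure; realizations failing phase 1 are recorded with a
sentinel p-value of 1, and `c₂` is the empirical α-quantile (inverse-ECDF)
of **all** recorded p-values.  This convention — rather than the
1−α quantile of the phase-2 p-values alone — is the one that makes the
unconditional null rejection rate equal α, which the self-consistency tests
verify directly.  Grid points with prevalence above 0.4, or where fewer than
1% of realizations advance (the α-quantile is then dominated by the
sentinel), fall back to the mean cutoff of the remaining points.  Lookups
use the nearest grid point with ties rounding down; no smoothing or
interpolation is applied.  The prevalence used at lookup time is the
group-count-weighted average of the two arms' Burrows estimates — the
natural plug-in for the common prevalence assumed by the null calibration;
indexing by a single arm's estimate would change results only through the
granularity of the grid.

### Competing designs and assay accounting

* **Case-control**: every individual × antibody combination is one assay;
  Fisher exact test at α per antibody.
* **Standard group testing**: pooled assays for every pool × antibody;
  every observed-positive pool is fully retested (k assays), reconstructing
  the individual data exactly at perfect sensitivity — significance calls
  are then bit-identical to case-control.
* **Two-phase**: pooled assays for every pool × antibody, retests only for
  advancing antibodies' observed-positive pools.  Both phases reuse the same
  pooled outcome realization (phase 2 retests the same physical pools), so
  on any shared realization the two-phase design never consumes more assays
  than standard group testing.

Dilution error is modeled as a loss of pooled-test sensitivity: a truly
positive pool tests negative with probability 1 − sensitivity, independently
across pools and antibodies.  Specificity is fixed at 1 (a configurable
field exists but the default reflects the assays being emulated), and
individual-level retests are assumed error-free — error is attributed to the
pooling step itself.  Members of missed (false-negative) pools are imputed
negative, which slightly depletes the reconstructed tables and lowers the
assay count.

## Synthetic cohort generator

Cohorts follow a probit random-effect model: individual `i` reacts to
antibody `j` with probability `Φ(α₀ⱼ + α₁ⱼ yᵢ + bᵢ)`, with per-antibody
intercepts `α₀ⱼ ~ N(−3, sd 0.5)`, a case effect `α₁ = 0.73` at the first
200 of 15,000 antibodies (zero elsewhere), individual random effects
`bᵢ ~ N(0, sd 2)` shared across all of an individual's antibodies
(exchangeable within-individual correlation), and independent Bernoulli
outcomes given the probabilities.  Defaults: 500 cases and 500 controls.

Both spread parameters are plain standard deviations.  The random-effect
scale must be an sd of 2: the marginal control prevalence is
`Φ(−3/√(1+σ₀²+b_sd²))`, which is ≈ 0.10 only under that reading.  For the
intercept spread, both sd = √0.5 and sd = 0.5 give marginal prevalence
≈ 0.095–0.10; the default is sd = 0.5 because the expected pool-positivity
rate it implies at pools of 5 (0.383, by Gauss–Hermite quadrature over the
intercept and random effect) matches the assay-count behaviour of the
published design comparisons, whereas sd = √0.5 gives 0.390.  Signal
antibodies occupy the first columns; power is evaluated over them and
type-I error over the rest, with no multiplicity adjustment (point-wise
error control).

What the generator does not emulate: assay normalisation and thresholding
of continuous reactivities (inputs are already binary calls), antibody
cross-reactivity structure beyond the single shared random effect, and any
covariate or batch structure.  Passing tests therefore demonstrate the
designs' statistical behaviour under exchangeable correlated binary
reactivities, not robustness to real-data artifacts such as plate effects.

## Numerical and scale choices

* **Fisher exact test**: implemented vectorised over tables with shared
  margins (hypergeometric pmf over the support, minlike rule with relative
  tie tolerance 1e−7, matching mainstream software), with a cache keyed by
  the table counts — the designs evaluate 10³–10⁵ tables per replicate
  against fixed arm sizes, so cached evaluation is what makes full-scale
  runs tractable.  Degenerate margins give p = 1.
* **Quantiles**: inverse-ECDF (type 1), reproducible across platforms;
  differences between quantile conventions are O(1/reps).
* **Seeding**: a seed ladder (master seed → per-replicate cohort seed →
  per-design stream) makes every run deterministic and lets designs share
  cohorts for paired comparisons; calibration grid points use seeds derived
  from (master seed, grid index), so the table is invariant to execution
  order.
* **Strict inequalities** throughout (`p < c₁` to advance, `p < c₂` /
  `p < α` to reject), consistently in calibration and analysis, so the
  calibration contract transfers to the analysis path exactly.
* **Monte-Carlo effort defaults** (the package's own evaluation scale):
  calibration uses 4,000 null realizations per grid point for the primary
  cutoff and 2,500 for sweep tables; power and type-I error are estimated
  on cohorts of 200 signal + 1,000–1,200 null antibodies over several
  hundred replicates; expected assay counts are measured on full
  15,000-antibody cohorts over 60–100 replicates.  Published-scale runs
  (10,000 calibration realizations per point, 1,000 full-cohort replicates)
  are supported by the same functions by raising `reps`.

## Known limitations

* Per-cohort operating characteristics vary substantially because the
  shared random effect correlates all antibodies within a cohort (the
  replicate-to-replicate standard deviation of the two-phase assay count is
  roughly 15% of its mean); many replicates are needed for tight Monte-Carlo
  error on expected counts.
* Under the cohort model the phase-1 screen advances slightly fewer null
  antibodies (≈ 26%) than under an i.i.d. null at the same prevalence
  (≈ 29% at `c₁ = 0.3`), because within-arm heterogeneity of pool-positivity
  probabilities underdisperses the pooled counts relative to the binomial
  model behind the z-test.  Realized type-I error of the calibrated
  two-phase test on cohort data is correspondingly a little below the i.i.d.
  calibration target.
* Under dilution error the type-I error rate rises slightly (0.046 → 0.052
  at sensitivity 0.95): missed pools bias the plug-in prevalence estimate
  down, so `c₂` is looked up at a lower grid point where the calibrated
  cutoff is looser.  Power is essentially unchanged (0.854 → 0.851) — the
  looser cutoff nearly offsets the signal lost to missed pools.  Published
  comparisons that report power *increasing* under dilution are not
  reproduced here; no mechanism for a genuine increase is apparent, and the
  corresponding acceptance test is deliberately left failing rather than
  retuned (see the comment in `tests/test_acceptance.py`).
* Unequal pool sizes (ragged last pool) are rejected rather than handled;
  the estimator as implemented assumes a single `k`.
* Pools never mix cases and controls, and no covariate adjustment or
  stratification is available.
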