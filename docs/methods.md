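# Methods

## The estimation problem

A 95% reference interval (RI) is the central 95% range of an analyte in a
healthy reference population; each reference limit (the 2.5th and 97.5th
percentile) carries its own sampling uncertainty. The question `risize`
answers is: how many reference subjects must be sampled before both limits
are estimated precisely enough? "Precisely enough" follows the established
rule that the 90% CI of a reference limit should be narrower than 0.2 times
the RI width.

## Procedure

For a candidate sample size n:

1. Draw B resamples of size n with replacement from the reference
   population (the population plays the role of the data-generating law;
   this is a bootstrap approximation to repeated cohort recruitment).
2. Compute the RI limits on each resample by the chosen estimator, giving B
   (lower, upper) pairs.
3. Take the 90% percentile CI of the B lower limits and of the B upper
   limits, and a scalar summary W of the B interval widths.
4. Form R1 = CI-width(lower)/W and R2 = CI-width(upper)/W; flag n as
   passing when both are below the threshold (0.2).

Sweeping n in ascending order gives a 0/1 flag sequence that is noisy near
the crossover. Two smoothing passes with window w = 10 — a moving sum of
the flags, then a moving median of the sums — define stability: the
estimate is the grid value at the first index where the moving median
equals w. Each smoothing pass shortens the sequence by w − 1, so the first
all-pass median index j is mapped back to the grid; the default
(`report_position="run_start"`) reports the start of the earliest window
contributing to that median, which is the beginning of the stable run. The
alternative mapping `window_end` (the grid point at which stability was
confirmed, 2(w − 1) grid steps later) is available because the back-mapping
after two smoothing passes is a genuine design choice; the two differ by at
most 2(w − 1) × step samples.

Non-convergence by the end of the grid is a first-class result (the
sentinel `None`, rendered `NC` in tables), not an error: whether an analyte
converges within the grid is a property of its variation.

## Estimators

**Transformed parametric.** Box–Cox with λ fitted by profile maximum
likelihood over λ ∈ [−5, 5] (bounded scalar minimization, tolerance 1e−5;
ties broken toward smaller |λ|, so exact log/identity transforms are
preferred when as good). Data containing values ≤ 0 are shifted by
1 − min(x) first. Limits are the back-transformed mean ± z·SD (sample SD,
ddof = 1) on the transformed scale, z = Φ⁻¹((1+level)/2) at full precision
(1.959964… for 95%). If the lower transformed limit falls outside the
transform's range (possible for λ > 0 under strong skew) it is clipped to
the domain boundary and the interval flagged rather than erroring. The
parametric arm always transforms — λ ≈ 1 reduces to the plain parametric
method on normal data — rather than gating on a per-sample normality test,
which would mix estimators within one bootstrap distribution. The
Kolmogorov–Smirnov (Lilliefors) normality report is therefore descriptive.

**Non-parametric.** Empirical quantiles under the package-wide convention:
linear interpolation of order statistics at rank r = p(n+1) (Weibull
plotting position, the CLSI convention for reference limits), ranks outside
[1, n] clipped to the extreme order statistics. The same convention is used
for bootstrap CIs, Tukey quartiles and width summaries, and is verified
against an independent sort-and-interpolate oracle in the tests.

**Inside the bootstrap**, the parametric fit runs vectorized: a
golden-section search maximizes the Box–Cox profile log-likelihood for all
B resamples simultaneously (42 iterations bring the bracket below 1e−5).
The batch fit and the scalar estimator maximize the same likelihood and
agree to the λ tolerance; a dedicated test compares them row by row.
Degenerate resamples (constant values, or a fit with non-finite limits) are
redrawn from the same seeded stream, up to 10·B total redraws, so B
effective replicates always back each candidate n; a constant resample is
legitimate for the non-parametric estimator (a zero-width interval).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| n_min, n_max, step | 40, 2000, 1 | candidate-n grid (analyte subjects) |
| B | 1000 | resamples per candidate n |
| ri_level | 0.95 | RI coverage |
| ci_level | 0.90 | limit-CI coverage |
| threshold | 0.2 | R1/R2 criterion |
| window | 10 | moving-window width for both smoothing passes |
| width_summary | median | scalar summary W of the B RI widths |

The width summary is configurable (`median`, `mean`, `quintile1..4` = the
20/40/60/80th percentiles) because a single scalar divisor must stand in
for "the quintiles of the widths"; the median is the robust default and the
quintiles support sensitivity analysis.

Randomness: a single root seed spawns one independent child stream per
(method, n) via `SeedSequence` spawn keys, so results are invariant to
evaluation order and to early stopping, and the validation re-run uses a
stream disjoint from the search by construction. With `early_stop` (default
on) the sweep halts once the first stable index is decided — the smoothing
only looks backwards, so the estimate cannot change with further points; a
full-grid trace for CI-width-vs-n plots needs `early_stop=False`.

Tukey outlier filtering (fences Q1 − 1.5·IQR, Q3 + 1.5·IQR on the raw
scale) is applied once to the population before any search, not inside the
bootstrap loop — per-resample filtering would change the resampling
distribution. It is skippable (`--no-tukey`): on strongly right-skewed data
the fences flag genuine tail values and pull the upper limit inward (shown
in `examples/02`).

## Synthetic populations

The generator emulates the structure of thyroid-panel reference data:
approximately normal analytes with small between-subject CVs (ft3_like
6.0%, ft4_like 7.7%, tt3_like 9.4%, tt4_like 6.4%) and a right-skewed
lognormal analyte (tsh_like, CV 35%). Presets fix only the CV and a
configurable location (default mean 1.0 in analyte units): the estimators
are location/scale-equivariant for the normal family and scale-equivariant
for the lognormal, so the CV is the driver of the required sample size.
Gamma and two-component normal-mixture families are available for
robustness studies; every family exposes analytic (or numerically inverted,
tolerance below 1e−8) true quantiles for recovery tests.

What the synthetic populations do **not** model: age/sex structure,
analytical imprecision layered on biological variation, within-subject
variation, or the mixture of unhealthy subjects that contaminates
real-world indirect datasets. Passing recovery tests on these populations
demonstrates the estimator's statistical correctness, not that a given
hospital dataset is a valid reference population.

## Numerical choices and degenerate inputs

* Quantile convention as above, everywhere; verified to 1e−12 against the
  oracle.
* Box–Cox round-trip inverse is exact to 1e−9 over the tested range
  (λ ∈ [−2, 2], x ≤ 100); for strongly negative λ and large x the
  transformed value intrinsically carries less than 1e−9 absolute precision
  in float64.
* Constant populations: the non-parametric RI is the zero-width interval;
  the parametric fit raises (likelihood undefined); the search marks such
  grid points degenerate with flag 0 — a 0/0 ratio never counts as
  converged.
* Normality on constant input reports non-normal with a note, no exception.

## Problem sizes in tests and the acceptance script

The reference settings (grid step 1, B = 1000) are the defaults. The test
suite and `scripts/acceptance.py` run the same machinery at reduced scale —
populations of 5000, B = 100–300, grid step 5–10 — which leaves every
qualitative conclusion (CI narrowing, method ordering, convergence
patterns) intact while keeping runs desk-scale; B affects only the Monte
Carlo noise of the ratios, not their location.

## Known limitations

* The estimate inherits the population's sampling noise: two different
  reference datasets of the same analyte give different estimates, and the
  validation ratios at the estimate are themselves stochastic (occasionally
  just above the threshold).
* Bootstrap CIs are percentile-type; no BCa or studentized variants.
* The linear sweep is faithful but not the fastest possible search;
  bisection would exploit the near-monotonicity of the flags but is not the
  procedure being characterized.
* The robust small-sample RI estimator and indirect (data-mining) RI
  methods are out of scope, as is partitioning by sex or age.
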