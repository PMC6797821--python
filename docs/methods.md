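# Methods

## Model and estimator

GSCA represents each construct as a *component*: an exact, unit-variance
weighted composite γ_p = Z w_p of its indicator block, with the data Z
column-standardized.  The model has three parameter matrices: weights W
(J × P, block-diagonal), loadings C (P × J, one free loading per indicator,
on its own component), and path coefficients B (P × P, free where the
structural diagram has an arrow).  Estimation minimizes

    f(W, C, B) = SS(Z − ΓC) + Σ_{q endogenous} SS(γ_q − Γ b_q),  Γ = ZW,

subject to var(γ_p) = 1 for every component.  Components with no incoming
paths contribute only measurement terms; their structural residual would be
the constant n and is omitted.

**Standardization.**  Columns are centered and scaled to sum of squares n
(divisor-n convention).  This makes the unit-variance normalization
diag(W′Z′ZW) = nI exact and lets the whole ALS run on the J × J sample
correlation matrix R = Z′Z/n: loadings are c_pj = (Rw_p)_j, path updates
solve small systems in K = W′RW, and each weight update needs only R.  A
bootstrap refit therefore costs O(nJ²) for the cross-products plus
O(J²)-per-iteration ALS work, independent of n in the iteration.

**ALS sweep.**  Each iteration updates (i) all loadings and paths by exact
per-column least squares given W, then (ii) each component's weights in
component order given everything else.  The weight subproblem — minimize f
over w_p subject to w_p′Rw_p = 1 — reduces to maximizing v′w_p under the
quadratic constraint, with closed-form solution w_p ∝ G⁻¹v (G the
within-block correlation block).  Because each substep is an exact
constrained minimizer, the criterion sequence is non-increasing; the tests
assert this at every iteration.  Singular within-block systems fall back to
the minimum-norm least-squares solution when the system is consistent
(perfectly redundant indicators stay estimable) and raise an
inadmissibility error otherwise.

**Convergence and initialization.**  Iteration stops when the absolute
decrease of f falls below `tol` (default 1e−5) or after `max_iter` (default
300) sweeps.  Weights initialize to equal values within each block,
rescaled to unit component variance; this is deterministic and adequate for
the model class studied here.  Seeded random restarts are available via
`GSCA(random_restarts=..., random_state=...)` for ill-behaved blocks.

**Sign conventions.**  Component signs are indeterminate.  On an original
fit, each component is flipped so the sum of its loadings is ≥ 0.  Every
bootstrap and jackknife refit is aligned to the original solution by
flipping any component whose weight vector has negative inner product with
the original's (an exact zero keeps the candidate).  Without this,
replicate distributions would be sign-flip bimodal and all intervals
meaningless.

## Bootstrap confidence intervals

All three methods consume the same B replicates θ̂*₁…θ̂*_B of each free
parameter; each replicate is a full pipeline re-run (row resampling with
replacement, column re-standardization, ALS refit, sign alignment).
Resamples on which the refit is inadmissible (a constant column, a
genuinely singular block, non-convergence) are redrawn with the next draws
of the same generator stream — not dropped — so exactly B replicates
always exist; the redraw count is recorded, and more than 10% failures
aborts as degenerate data.

* **Percentile.**  1-based order-statistic indices j = round(B·α/2) and
  k = round(B·(1−α/2)), rounded half-up and clamped to [1, B].  With
  B = 1000 and α = 0.05 this is the 25th and 975th order statistic.
  `B·α/2 < 1` is an error (too few resamples to estimate the tail).
* **BCa.**  ẑ₀ = Φ⁻¹(c/B) with c the count of replicates *strictly* below
  θ̂ (ties uncounted), clamped to [0.5, B−0.5] so ẑ₀ stays finite.  The
  acceleration â comes from one leave-one-out jackknife pass per original
  sample (n refits, reused for all parameters), â = Σd³/(6[Σd²]^{3/2}) with
  d_i = θ̂(·) − θ̂(−i), and â = 0 when all jackknife values tie.  Adjusted
  levels α₁ = Φ{ẑ₀ + (ẑ₀+z^(α/2))/(1 − â(ẑ₀+z^(α/2)))} and the analogue at
  z^(1−α/2) pick order statistics with the same rounding rule.  When
  ẑ₀ = â = 0 the construction reduces exactly to the percentile interval;
  a 1e−9 guard in the rounding keeps that reduction exact through
  floating-point round-trip of Φ∘Φ⁻¹.
* **Student's t.**  θ̂ ± t_{n−1}(1−α/2)·se, where se is the replicate
  standard deviation with divisor B−1 and n is the original sample size.
  The same se feeds the critical ratio θ̂/se.

The interval machinery is generic over any statistic (`bootstrap_statistic`,
`jackknife_statistic`); the test suite exploits this to calibrate all three
methods on the sample mean of i.i.d. normal data, where the answer is known.

## Population model

Six latents: γ₁–γ₄ exogenous, γ₅–γ₆ endogenous; three indicators per
latent with standardized loadings (0.7, 0.8, 0.9); structural paths

    γ₅ = −0.25·γ₁ − 0.20·γ₂ + 0.55·γ₃ + ζ₅
    γ₆ = −0.75·γ₁ + 0.35·γ₄ − 0.15·γ₅ + ζ₆

with exogenous correlations 0.6 throughout except corr(γ₃, γ₄) = 0.5, and
residual variances chosen so every latent has variance 1.  This wiring was
reconstructed to reproduce the documented explained variances: it implies
R² = 0.168000 for γ₅ and 0.382975 for γ₆.  The implied latent correlation
matrix is solved recursively in topological order; inconsistent
coefficients (explained variance ≥ 1) are rejected.

**Indicator covariance (component construction, the default).**  A coverage
study is only interpretable if the estimator is consistent for the
parameters whose coverage is scored.  For a composite-based estimator that
requires a composite-based population: within each block the unit-diagonal
correlation matrix is chosen so that the block loading vector λ is its top
eigenvector with eigenvalue λ′λ (for λ = (0.7, 0.8, 0.9): off-diagonals
0.269, 0.492, 0.627), and between blocks Σ_pq = φ_pq λ_p λ_q′.  Under this
Σ the population weights are w = λ/(λ′λ), the population composite
reproduces exactly the stated loadings and paths, and the ALS run on Σ
itself returns them to numerical precision (a test asserts this).  An
alternative factor-structured mode (`structure="factor"`: within-block
λ_iλ_j, unique variances 1−λ² on the diagonal) is provided for studying the
composite-vs-factor discrepancy; under it, composite loadings exceed the
factor loadings by up to +0.12 and paths are attenuated by up to 0.18, so
it is *not* used for the coverage study.

**Generators.**  `generate_normal` mixes i.i.d. standard normal rows with
the lower Cholesky factor L of Σ (X = EL′).  `generate_lognormal`
exponentiates independent standard normals, standardizes each column
(divisor n), then applies the same mixing; the marginals are strongly
right-skewed and heavy-tailed while the covariance matches Σ in
expectation.  Moments use the raw standardized-moment conventions: skewness
m₃/m₂^{3/2}, kurtosis m₄/m₂² (normal ⇒ 3, no excess adjustment), with
divisor-n central moments.

Skewness and kurtosis summaries are reported as within-condition averages
over indicators and replications.  Per-indicator extremes are not a
meaningful summary for a Cholesky-mixing generator: the first column of the
mixed matrix is an unmixed lognormal variate whose sample skewness dwarfs
every other column, so only the indicator-averaged level characterizes a
condition.  Because sample moments of heavy-tailed data are strongly
downward-biased at small n, the condition averages rise with n by design.

**What the generator does not emulate.**  Real questionnaire data are
bounded, discrete (Likert-type), and heteroskedastic across items; the
generator produces continuous unbounded indicators with a single
non-normality mechanism (lognormal transformation).  Passing coverage tests
here therefore speak to the interval constructions under clean composite
populations, not to robustness against discreteness, outliers, or model
misspecification.

## Simulation harness and evaluation

A `SimulationDesign` crosses distributions × sample sizes (defaults: normal
and lognormal × n ∈ {50, 100, 200, 500}, 500 replications, B = 1000,
α = 0.05, all three methods).  Each replication derives its seed as
`master_seed + condition_offset + replication_index`, so any cell is
reproducible in isolation and the full study is a pure function of the
design.  Results persist as one long-format CSV row per (condition,
replication, parameter, method) plus a manifest (design, seeds,
per-cell convergence and redraw counts); scoring is a pure function of that
file.  The jackknife for BCa runs once per replication on the original
sample — the BCa formulas require nothing else, and anything per-resample
would be computationally prohibitive.

Coverage scoring uses inclusive endpoints (lower ≤ θ ≤ upper); the
distinction is measure-zero and fixed for determinism.  Coverage,
miss-below (θ < lower) and miss-above (θ > upper) partition 1 exactly.
Aggregation is unweighted: loading summaries average the six per-latent
entries sharing a population loading value; path summaries average over
whatever conditions share a population path value.

**Problem sizes in the tests.**  The test suite runs a scaled-down study —
two conditions (normal and lognormal at n = 100), 100 replications,
B = 200 — chosen as the smallest design in which the binomial 3σ band
around 0.95 (±0.065 at 100 replications) is still informative.  Interval
calibration is additionally checked on the sample mean (n = 50, 1000
trials, B = 399), where all three methods must land in [0.92, 0.975].
Homogeneous-loading populations (all 0.7, all 0.8, all 0.9) are available
through `build_population(loadings=...)` for the alternative reading of the
loading design.

## Known limitations

* The structural wiring and exogenous correlations are a reconstruction
  constrained by the two implied R² values; other wirings satisfy the same
  constraints, and downstream quantities that depend on the full Σ (e.g.
  the exact moment levels of the lognormal generator) vary across
  reconstructions by on the order of 10–20%.
* No missing-data handling; inputs must be complete.
* No regularized, uniqueness-term, multilevel, clusterwise or dynamic GSCA
  variants; no basic/reverse-percentile or studentized (per-resample SE)
  intervals.
* Execution is serial; determinism under a fixed seed is the only
  concurrency guarantee.
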