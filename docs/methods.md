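# Methods

## Model and procedure

The package studies global-null testing with combined p-values on count
data.  One simulation replicate is built in four stages:

1. **Dependent uniforms.**  An n × m matrix U is drawn from an
   exchangeable Archimedean copula.  Sampling uses the Marshall–Olkin
   frailty construction, which is exact and O(n·m):
   - *Clayton(θ), θ > 0*: V ~ Gamma(shape 1/θ, rate 1), Eᵢ ~ Exp(1)
     i.i.d., Uᵢ = (1 + Eᵢ/V)^(−1/θ).  Lower-tail dependence.
   - *Gumbel-Hougaard(θ), θ ≥ 1*: V positive α-stable with α = 1/θ via
     the Chambers–Mallows–Stuck representation, Uᵢ = exp(−(Eᵢ/V)^(1/θ)).
     Upper-tail dependence.  θ = 1 branches explicitly to i.i.d.
     uniforms because the stable sampler is singular at α = 1.
   - *Survival Clayton*: the elementwise complement 1 − U of a Clayton
     draw (upper-tail dependence).  With a shared seed it is exactly
     1 − Clayton, which the tests assert bitwise.
   - Kendall's τ closes the parameterization: τ = θ/(θ+2) (Clayton and
     survival Clayton), τ = 1 − 1/θ (Gumbel-Hougaard).
   Correctness of the samplers is asserted distributionally (marginal
   uniformity by Kolmogorov–Smirnov, τ recovery within 3 Monte-Carlo
   standard errors, tail-dependence asymmetry) and cross-checked against
   statsmodels' independent Clayton sampler.

2. **Count margins.**  Each column is pushed through the negative
   binomial quantile function (failures convention; r may be
   non-integer, the pmf uses the gamma-function binomial coefficient).
   The quantile is the left-continuous generalized inverse, the smallest
   x with CDF(x) ≥ u.  Inside Monte-Carlo loops it is evaluated as
   `searchsorted` against a precomputed CDF table (covering all u below
   1 − 1e−13, with a scipy `ppf` fallback beyond); the table path is
   asserted identical to `scipy.stats.nbinom.ppf` and to a linear-scan
   oracle.  Being monotone, the transform preserves within-column
   ordering, so copula concordance carries over to the counts up to
   ties.

3. **Individual tests.**  Per variable, the two-sided Z-test
   Z = (x̄ − μ₀)/√(V₀/n), p = 2[1 − Φ(|Z|)].  V₀ is the *theoretical
   null* variance r₀(1−p)/p², not the sample variance: the null fixes
   the complete marginal law, and parameterizing by (μ₀, V₀) keeps the
   test correct for p ≠ 0.5 even though all study scenarios use p = 0.5
   (where μ₀ = r₀ and V₀ = 2r₀).

4. **Combination.**  Equal-weight CCT, Fisher, and MinP on the m
   p-values; a replicate rejects at level α when the combined p-value
   falls below α.  The rejection proportion over M replicates estimates
   the size (all-null configuration) or power (signal configuration),
   with binomial standard error √(rate(1−rate)/M).

## Numerical choices

- **Clipping.**  Input p-values (and copula uniforms) are clipped to
  [1e−15, 1 − 1e−15] before the tangent/log transforms, avoiding ±∞
  while preserving order.  How p = 0 or 1 should be treated is otherwise
  an open convention; clipping is the least surprising choice.
- **Cauchy tail.**  The direct P = 0.5 − arctan(Ψ)/π cancels
  catastrophically for large |Ψ|; above |Ψ| = 1e8 the implementation
  switches to the tail identity P ≈ 1/(πΨ) (and 1 − 1/(π|Ψ|) on the
  left).  At the crossover the two branches agree to ~1e−17 absolute,
  far below any tolerance used.
- **MinP.**  1 − (1 − p₍₁₎)ᵐ is computed as −expm1(m·log1p(−p₍₁₎)) so
  tiny minima are not lost to cancellation.
- **Weights.**  User weights are normalized to sum to one rather than
  rejected (applications routinely pass unnormalized weights); Fisher
  and MinP are defined unweighted and ignore them, recording
  `weights_applied=False` in the result.
- **RNG contract.**  Every scenario spawns one `SeedSequence` substream
  per replicate from its root seed, so identical configurations give
  bit-identical tables and any execution order (or chunking) yields the
  same aggregates.  Replicates are processed in blocks of 500 to bound
  memory.

## Default study conditions

The simulator's defaults are the study conditions themselves: p = 0.5,
n = 30, M = 10,000 replications, α ∈ {0.05, 0.01}, m ∈ {10, 50, 100}
with r ∈ {5, 30, 50} for the independent size study; copula strength
θ ∈ {1, 3, 5} for the dependence study; and the sparse-signal power
layout of nine null variables at r = 10 plus one signal at r = 11
(effect size one count, i.e. (11−10)/√(20/n) standard errors), all
Z-tests run against null mean 10, swept over
n ∈ {5, 10, 30, 50, 100, 150, 200, 300, 500, 1000} at α = 0.05.
M = 10,000 is the replication count attached to every reported table.

The standardized-skewness diagnostic γ/√n, γ = (2−p)/√((1−p)r) — the
skewness of the sampling distribution of the mean — is the practical
validity guideline: the CCT's size is near nominal once γ/√n ≲ 0.05
at m = 30 combined tests (stricter for larger m).  It is displayed
rounded to two decimals in the sensitivity table.

## Scaled-down defaults in the test suite

The test suite reruns the pipeline at reduced problem sizes chosen so
the whole suite completes in well under a minute while every comparison
retains a 3-standard-error margin: the two headline independent size
cells run at the full M = 10,000, the dependence-ordering and power
checks at M = 2,000, copula diagnostics at n = 5,000–10,000 draws.
Full-scale runs of any table remain one CLI flag away
(`cctcount type1 --replications 10000 ...`).

## What the simulations do and do not show

The generator emulates exchangeable dependence with a single tail-heavy
parameter θ and identical negative binomial margins per scenario.  Real
count data depart from this in ways the study deliberately abstracts
away: heterogeneous library sizes and margins, non-exchangeable
correlation (e.g. block or banded structure), zero inflation, and
estimated rather than known null variances.  Passing tests therefore
show that the combination tests behave as published *under the stated
copula/NB conditions*, not that the CCT is calibrated for any particular
real dataset.  The meta-analysis worked examples use the published
per-study p-values as-is; nothing is re-derived from the underlying
studies.

## Known limitations

- The Z-test uses the known-variance normal approximation; for small n
  or small r its p-values are discrete and conservative, which is
  precisely the regime the sensitivity analysis maps out.
- Copula parameter estimation, non-Archimedean families (Student-t,
  vine copulas), and alternative count margins (Poisson-inverse
  Gaussian, Sichel) are out of scope.
- The heatmap's full 1000-fold outer averaging is CLI-reachable but not
  run by default; the tests exercise the reduced form.
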