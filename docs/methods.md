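# Methods

## Design representation

A trial is a `DesignLayout`: `T` calendar periods, `S` sequences with
strictly increasing crossover periods (sequence *s* of the standard wedge
crosses at period *s + 1*; the value `T + 1` encodes a never-crossing
comparator), `m_s` clusters per sequence, a per-cluster cohort of `N_i`
individuals split `(N_i0, N_i1)` between the IL arms.  With an odd cohort
and a 50/50 split the treated arm receives the extra individual
(`N_i1 = ceil(N_i/2)`), a deterministic rule chosen for reproducibility.

All per-cluster matrices share one row ordering: individual-major,
period-minor, IL-control individuals first.  Cross-sectional sampling is
encoded as an open cohort in which each individual is observed in exactly
one period, so one incidence mechanism covers all three cohort types.
Incompleteness is a row-selection operator `S` derived from the incidence
matrix `K_i` (closed cohorts use the Kronecker construction
`K_i = K_s ⊗ 1_{N_i}`); it acts as `S X` on the design matrix and `S R Sᵀ`
on the correlation matrix, the standard treatment of planned missingness in
a GEE calculation.

## Mean model

Exposure bookkeeping: at period `j`, `A^CL = max(0, j - crossover + 1)`;
an IL-treated member of a closed cohort has `A^IL = j` (both randomizations
happen concurrently at study start, so the IL clock starts at baseline);
`A^Int` counts the periods in which both exposures were simultaneously
active, which for baseline-randomized IL equals `A^CL` on the treated arm.
The IL clock for individuals joining mid-study is not well defined by the
design itself and is deliberately left to explicit configuration rather
than guessed.

The incremental model's interaction covariate is the cumulative
joint-exposure count scaled by `c_Int` — not the product `A^IL · A^CL`,
which would grow quadratically in calendar time and change the coefficient's
meaning across the study.  Categorical time trends use reference-period
coding (the intercept absorbs period 1); polynomial trends use raw powers of
the 1-based period index so coefficients remain interpretable.  Identity,
log and logit links are supported with gaussian, poisson and binomial
variance functions.

Identifiability caveat: with a *single* sequence the incremental CL
covariate is an affine function of calendar time, so it cannot be separated
from a linear time trend; likewise a cluster whose cohort is entirely in one
IL arm cannot separate the IL effect from time.  The engine detects such
designs and raises an error naming the non-identified columns instead of
returning a near-singular inverse.

## Correlation and covariance

Block exchangeable correlation: 1 on the diagonal, `alpha2` for the same
individual across periods, `alpha0` for different individuals in the same
period, `alpha1` otherwise.  The block autoregressive variant decays the
within-individual entry as `alpha2^|lag|`; whether the inter-individual
inter-period correlation also decays is not fixed by convention, so it is a
config switch (`decay_inter_period`, default off, giving the common
block-exchangeable behaviour between individuals).  Positive definiteness is
checked by attempted Cholesky factorization with an eigenvalue fallback at
tolerance 1e-10, so a bad `alpha` fails early with the offending parameters
and dimensions in the message.  The working covariance is
`V = phi · A^{1/2} R A^{1/2}`, `A = diag(v(mu))`, computed via a bitwise
symmetric outer product so `V = Vᵀ` holds exactly.

## Power

`Omega = (Σ_i D_i' V_i^{-1} D_i)^{-1}` with `D_i = Δ_i X_i` and
`Δ_i = diag(dmu/deta)`.  Identical clusters (same sequence, cohort
composition and observation pattern) share one information contribution, so
the worked example costs five dense solves rather than sixty-five.  The Wald
test of `H0: L θ = ℓ` uses
`λ = (Lθ - ℓ)' [L Ω L']^{-1} (Lθ - ℓ)`; attained power is
`P(χ²_{q,λ} > χ²_{q,1-α})` or, by default,
`P(F_{q,I-d,λ} > F_{q,I-d,1-α})` with `I - d` denominator degrees of
freedom — stepped wedge trials typically randomize few clusters, and the
t/F reference reflects that extra uncertainty (for `q = 1` it equals the
two-sided noncentral-t test).  The same `I - d` is used for incomplete
designs; per-cluster observation counts do not enter the degrees of freedom.
Kauermann–Carroll and Fay–Graubard small-sample corrections are out of
scope; `wald_power` is the hook point where an adjusted covariance or
degrees-of-freedom estimate would plug in.

Multiplicity: each contrast either carries its own significance level or a
family-wise level is split equally (Bonferroni); supplying both is rejected
as contradictory.  In the packaged example the secondary-aim tests are read
as *per-test* alpha = .1.

The sample-size search exploits monotonicity of power in the cohort size
(exponential bracketing plus bisection, with a linear-scan fallback if
non-monotone behaviour is ever detected).  When the number of clusters is
not divisible by the number of sequences, the frontier distributes the
remainder to the earliest sequences — deterministic and stated, rather than
an arbitrary tie-break.

## Simulation validation

`simulate_outcomes` draws Gaussian clusters exactly from the marginal model
(mean `X_i θ`, covariance `phi A^{1/2} R A^{1/2}`); binary outcomes use a
Gaussian copula whose latent correlation equals the target Pearson
correlation — a first-order approximation whose error grows with `|alpha|`
and with means far from one half, and which is documented as approximate
rather than exact.  `empirical_power` fits each replicate by GLS with the
*true* correlation plugged in: that is exactly the estimator whose
model-based covariance the power formula describes, so the comparison
isolates the power formula from correlation-estimation noise.  Replicates
are driven by per-replicate child streams spawned from one master seed, so
any replicate is reproducible in isolation.  The generator emulates the
marginal model faithfully but not features of real trials — dropout,
noncompliance, informative cluster sizes, secular shocks — so agreement
between analytic and empirical power validates the mathematics, not the
design assumptions.

Problem sizes used by the test suite and the acceptance script (a few
thousand Gaussian replicates of the 65-cluster example; dense-oracle checks
at `I ≤ 4`, `N ≤ 3`, `T ≤ 4`) were chosen so the whole suite runs in about
a minute on one core while keeping Monte-Carlo standard errors near one
percentage point.

## The packaged worked example, and a known discrepancy

`diabetes_example` encodes a six-period, five-sequence, 65-cluster closed
cohort with incremental effects `(0.1, 0.15, -0.1)` scaled to three periods,
block-exchangeable correlations `(0.05, 0.025, 0.5)`, identity link and unit
dispersion, a combined-effect test at alpha .05 and component tests at
alpha .1.  Under this configuration the engine gives powers of 74.1%
(combined), 73.7% (IL), 75.3% (CL) and 40.0% (interaction) at 15 individuals
per cluster, and the smallest cohort meeting 80% on the three goal tests is
19 (chi-square reference; 20 under the small-sample F).

This example follows a published illustration of the same design, which
reports a solution of 15 per cluster with powers of roughly 81/95/80/40
percent.  Those figures could not be reproduced from the stated inputs by
this implementation, nor by any variant we examined systematically
(alternative exposure clocks and scaling constants, average-effects and
mixed effect forms, every positive-definite permutation of the correlation
triple, autoregressive and cross-sectional correlation variants, sandwich
covariances under misspecified working correlation, categorical or absent
time trends, alternative multiplicity readings, and chi-square, F and
one-sided normal power approximations).  Notably, the interaction power of
40% is matched *exactly* by this implementation at alpha .1, while matching
the remaining three figures simultaneously would require the IL coefficient's
variance to be exactly halved and the CL coefficient's variance scaled by
about 1/1.145 — a pattern consistent with no principled construction we
could find.  Our own Monte-Carlo validation (exact Gaussian simulation plus
GLS with known correlation) confirms the analytic covariance to within
Monte-Carlo error, so we report the values our calculation produces and
flag the discrepancy rather than tune toward the published figures.

## Known limitations

- Model-based covariance only: the power calculation assumes the working
  correlation is correct; sandwich-variance power for misspecified
  correlation is out of scope.
- No estimation from data: `alpha`, `phi` and `theta` are design inputs, and
  the package does not analyse completed trials.
- The binary copula generator approximates, and slightly attenuates, extreme
  correlation structures.
- Spline/kernel time trends, cost-optimal designs, randomization-based
  inference and noncompliance are not implemented.
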