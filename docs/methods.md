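# Methods

## Model

Observations are rows `Y_i` of an `N x J` matrix, each belonging to one of
`K` groups (plots in squares, sites in regions). The structured model is a
multivariate random-intercept model:

- likelihood: `Y_i | group k ~ MVN(mu_k, Sigma)`, with a common `J x J`
  within-group covariance `Sigma`;
- intercept prior: `mu_{j,k} ~ N(0, eps)` independently over variables `j`
  and groups `k`. No overall per-variable mean is estimated; `eps` absorbs
  variability of means both between groups and between variables, which
  makes `eps` itself hard to interpret but keeps all within-group
  covariance in `Sigma`;
- precision prior: `Omega = Sigma^{-1}` is Wishart with density
  `|Omega|^{(nu0-J-1)/2} exp(-tr(R0 Omega)/2)`, `nu0 = J + 1`,
  `R0 = Sigma_R` (the pooled raw-data sample covariance, denominator
  `N - 1`). With no group structure the posterior of `Sigma` converges on
  `Sigma_R`.

The *empirical* model is the same with `K = 1`: pooled estimation that
ignores grouping. The hypervolume is the level-0.95 confidence ellipsoid of
`(mu, Sigma)`; for the structured model the center is the unweighted
average of the group means.

### Wishart convention

Common MCMC dialects disagree about whether the Wishart "scale" argument is
a scale or a rate. This package fixes the *rate* convention above
(`E[Omega] = nu0 * R0^{-1}`, i.e. the prior precision is centred on
`Sigma_R^{-1}`). The prior carries only `nu0 = J + 1` pseudo-observations,
so the choice is weak: a test (`test_prior_rate_convention_is_weak`)
refits with the rate replaced by its inverse and shows the posterior mean
volume moves by well under 10% at `N = 200`. The `rate_matrix` argument of
the fit functions exposes the override.

## Sampler

Both conditionals are conjugate, giving an exact two-block Gibbs sampler:

1. `mu_k | Omega, Y ~ MVN(P_k^{-1} Omega s_k, P_k^{-1})`,
   `P_k = n_k Omega + eps^{-1} I`, `s_k` the within-group sum;
2. `Omega | mu, Y ~ Wishart(nu0 + N, (R0 + S)^{-1})`, `S` the scatter of
   residuals about the current group means, drawn via the Bartlett
   decomposition.

There is no tuning, no accept/reject step, and no external MCMC runtime.
Chains initialize at the group sample means and at `Sigma_R^{-1}`
(ridge-stabilized by `1e-8 * mean(diag Sigma_R) * I` when needed), i.e. in
the posterior bulk. All `(J, J)` operations are batched across chains — and,
inside the simulation engine, across replicates — with stacked linear
algebra, which is what makes 100-replicate scenario cells run in seconds.

Defaults follow standard practice for this model family: 100,000
iterations, 50,000 burn-in, 3 chains, thinning 10. `eps` is a fixed
constant (10,000), not an estimated hyperparameter: on centered data it is
weakly informative at any realistic scale. A configuration must retain at
least 100 draws per chain.

### Diagnostics

`gelman_rubin` implements the classic potential-scale-reduction factor
(between/within chain variances, no rank normalization) for every group
mean and every upper-triangular element of `Sigma`; `check_convergence`
warns at the conventional 1.1 threshold. One test cross-checks the
statistic against `arviz.rhat` on stationary chains and against a hand
computation on divergent ones. Note that because the sampler is conjugate
it forgets its initial state within a handful of sweeps; even deliberately
short runs usually pass R-hat, so the warning path is exercised on
constructed non-stationary ensembles (and, in the CLI, via the
`--rhat-threshold` option).

## Geometry

- **Volume.** With eigenvalues `lambda_i` of `Sigma` and `c` the level
  quantile of chi-square(`J`), semi-axes are `sqrt(c * lambda_i)` and the
  volume is `U_J * c^{J/2} * sqrt(det Sigma)` (`U_J` the unit-ball
  volume).
- **Inclusion.** For an MVN, ordering by density equals ordering by
  Mahalanobis distance, so the probability of inclusion of a point with
  squared distance `d^2` is analytically `1 - F_chi2_J(d^2)`. The
  Monte-Carlo version (simulate draws, compare densities; ties count as
  more extreme) exists because it is the definition that generalizes, and
  is tested against the analytic form. Posterior propagation computes `p`
  per retained draw (pooled mean as center) and summarizes by mean or
  median.
- **Overlap.** Points are simulated from each hypervolume as the fitted
  normal *truncated* to its 95% ellipsoid (rejection sampling; acceptance
  rate = level). The hypervolume is the ellipsoid, so two identical
  hypervolumes overlap at exactly 1. Membership of a simulated point in the
  other hypervolume uses the analytic Mahalanobis test — the same decision
  boundary as a nested Monte-Carlo inclusion test at threshold 0.05,
  without the second simulation layer. The symmetric overlap is
  `(count_a_in_b + count_b_in_a) / (2 n)`; both directional containments
  are always reported, since asymmetric nesting (one habitat's volume
  almost inside another's) is often the scientifically interesting figure.
  Both hypervolumes are sampled from the same seed, making
  `overlap(a, b) == overlap(b, a)` exact at matched seeds.
- **Point estimates.** Volumes are reported as the posterior mean of
  per-draw volumes (the volume is a nonlinear functional of `Sigma`;
  averaging draws respects that). The alternative — volume of the
  posterior-mean `Sigma` — is also emitted by the CLI for comparison.
  Overlap uses the posterior-mean `(mu, Sigma)` hypervolumes.

## Synthetic-data generator

`simulate_grouped_dataset` draws group means i.i.d. `N(0, sigma2_b)` per
variable and group (no between-group correlation structure, matching the
intercept prior's univariate form) and observations
`MVN(mu_k, s_k * Sigma_true)`. Defaults define the study conditions:
`J = 3`, `K = 4`, `n = 10` per group, `sigma2_b = 2`, and `Sigma_true`
exchangeable with unit variances and correlation 0.5 — a moderately
correlated, well-conditioned matrix typical of co-varying ecosystem
properties; the test suite also exercises diagonal and anisotropic
matrices. The unequal-variance violation uses multipliers `s_k` evenly
spaced on `[0.5, 2]` (a 4x violation of the shared-covariance assumption).
Values outside the evaluated design ranges (`J` 3–7, `K` 4–10, `n` 10–50,
`sigma2_b` 0–2) are allowed but warned about.

What the generator does *not* emulate: non-normal margins (skewed traits,
zero-inflated indices), temporal autocorrelation, unbalanced group sizes,
measurement error, and uncertainty in group membership. Passing tests
therefore demonstrate correct behaviour of the estimators *under the
model's own assumptions* (plus the variance-scale violation); they do not
certify performance on real survey data with non-Gaussian structure.

## Simulation engine

For each replicate: simulate, center, fit both models, record
`(estimated - true)/true` where the true volume comes from `Sigma_true`.
Scenario cells default to 50 replicates with reduced MCMC (10,000
iterations, 5,000 burn-in, 2 chains) — sizes chosen so a full
between-group-variance grid runs in about a minute while medians are
stable; replicates whose R-hat exceeds 1.1 are excluded from medians and
counted. Per-replicate failures (degenerate data, non-finite draws) are
recorded, and a cell fails only if more than 20% of its replicates do.
Grid runs write tidy per-rep rows incrementally and resume by skipping
completed `(scenario, rep)` cells.

Observed pattern (recomputed by `scripts/acceptance.py` and the acceptance
tests): at `sigma2_b = 0` both estimators slightly underestimate the
volume (finite-sample determinant bias) and agree closely; as `sigma2_b`
grows the empirical estimator's median relative error rises monotonically
(far above +0.3 at `sigma2_b = 2`) while the model-based median stays
within ±0.3, and it remains the better estimator under the 4x
unequal-variance violation.

## Numerical choices and edge cases

- Sample covariance uses `N - 1`; data with `N < J + 1` are rejected
  (covariance singular by construction) and `N < J + 2` is warned about.
- Singular or indefinite `Sigma_R` (constant or collinear columns) is a
  hard error: it must serve as a Wishart rate.
- Centering subtracts grand means per variable (group shifts belong to the
  intercepts); standardization to unit variance is opt-in and off by
  default, so hypervolume axes keep their measurement units. Missing
  values are rejected, not imputed — the model has no missingness
  mechanism.
- Density ties in the Monte-Carlo inclusion test count as "more extreme"
  (a probability-zero event; fixed for determinism).
- All randomness flows through explicit integer seeds; identical
  configuration and data reproduce draws bit-identically.
- A single variable (`J = 1`) is accepted with a warning; a single group
  reduces the structured model exactly to the empirical one.

## Known limitations

- Normal likelihood only: no copulas, no non-nested or temporal random
  effects, no estimation of `eps`.
- Exact ellipsoid–ellipsoid intersection volumes are not computed; overlap
  is Monte-Carlo with a reported standard error.
- Posterior-mean point estimates are used for overlap; the per-draw
  uncertainty interval on overlap itself is not yet propagated.
- Performance beyond `J = 7` dimensions is untested; high-dimensional use
  would need substantially more data than typical ecological designs
  provide.
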