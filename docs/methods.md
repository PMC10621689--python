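# Methods

## The measurement problem

Forced-choice (FC) questionnaires ask respondents to rank the items of a
block rather than rate each item on a scale. This removes rating-scale
biases and, when the items of a block are equally desirable, resists
faking — but the resulting data carry only *comparative* information.
Classical point-assignment scoring of such data is ipsative: every
respondent's trait scores sum to the same total, so scores support only
within-person comparisons. Thurstonian item response theory (T-IRT) models
the latent utilities behind the rankings and promises normative scores.
`tirtsim` implements a controlled simulation laboratory for this question:
how reliable and how (non-)ipsative are classical and T-IRT scores across
trait counts, sample sizes, factor-loading regimes, keying schemes and
intertrait-correlation structures?

## Generative model

Person `p` assigns item `i` a latent utility

    t_pi = mu_i + lambda_i * eta_a(i),p + eps_pi,     eps_pi ~ N(0, psi_i^2)

where `a(i)` is the trait item `i` measures, `eta_p ~ MVN(0, Phi)` with a
correlation matrix `Phi` (traits standardized for identification), and
`psi_i^2 = 1 - lambda_i^2` because utilities are standardized. Each triplet
block is ranked by descending utility; a ranking is equivalent to three
binary outcomes `y_pik = 1{t_pi >= t_pk}`. Marginally each outcome follows
the probit law

    P(y_pik = 1) = Phi((-gamma_ik + lambda_i eta_a - lambda_k eta_b)
                       / sqrt(psi_i^2 + psi_k^2)),   gamma_ik = -(mu_i - mu_k),

but outcomes within a block are dependent, because one error draw per
person x item is shared by the three comparisons. The simulator draws the
error once per person x item, so that residual dependency is present in the
generated data exactly as the theory prescribes.

### Questionnaire construction

* Triplet blocks, items of one block on three distinct traits, 9 blocks per
  trait by default (27 items per trait-decade of design size). Trait
  pairings are deliberately *not* balanced: blocks are filled sequentially
  with distinct traits drawn proportionally to their remaining quota (any
  trait whose quota equals the number of remaining blocks is forced in,
  keeping the assignment feasible), and the block order is shuffled.
* Loading magnitudes come from one of two regimes: `high_uniform`,
  U(0.65, 0.95), the optimistic level used in early FC simulations; or
  `realistic_truncnorm`, N(0.5, 0.16^2) truncated to [0.1, 0.9], matching
  the loading distribution of a broad-band 30-facet personality inventory.
  Truncation is implemented by rejection (the acceptance rate is ~0.98).
* Keying: `equal` leaves all loadings positive; `mixed` negates a uniformly
  random subset of exactly floor(n/2) items.
* Item means are drawn `mu_i ~ U(-0.5, 0.5)` and pair intercepts derived as
  `gamma_ik = -(mu_i - mu_k)`. Drawing the *item means* rather than
  independent per-pair intercepts keeps every `gamma` in (-1, 1) while
  guaranteeing within-block additivity (`gamma_13 = gamma_12 + gamma_23`),
  which utility-based ranking generation requires. The price is that the
  marginal distribution of `gamma` is triangular on (-1, 1) rather than
  uniform — a documented deviation, chosen because an internally
  inconsistent set of intercepts cannot drive a ranking simulator.
* Intertrait correlations: `zero` (identity), `matrix_file` (a headerless
  CSV correlation matrix supplied by the user, e.g. an empirical 30-facet
  matrix), or `neo_like`, a synthetic stand-in with the hierarchical
  structure of a five-domain x six-facet inventory (within-domain
  correlations U(0.3, 0.6), between-domain U(-0.2, 0.3), projected to the
  nearest correlation matrix). For fewer than 30 traits a principal
  submatrix is extracted with facet counts balanced across domains
  (difference at most 1) and a rotation offset `(replication - 1) mod 6` so
  the six replicate submatrices of a condition differ deterministically.

## Scoring procedures

**Classical.** Rankings are first expanded to binary paired comparisons.
Each comparison awards points to the traits of the two items according to
the items' keyed signs: preferring a positively keyed item — or rejecting a
negatively keyed one — is evidence for a high standing on its trait. With
equally keyed items every comparison awards exactly one point in total,
which makes per-person totals constant (`3 x n_blocks`): fully ipsative
scores. Raw scores are z-standardized column-wise (population-SD
convention) before RMSE is computed; the squared correlation with the truth
is unaffected by this affine transform. The scale convention is the
package's own choice — some scale-free convention is needed to compare an
integer point total with z-scaled latent traits, and in-sample
z-standardization is the simplest one.

**Bayesian T-IRT.** The estimator treats the latent utilities as augmented
data (the probit data-augmentation tradition): conditional on everything
else, each utility is a normal truncated to the observed within-block
ordering, giving a Gibbs sampler:

1. utilities `t` — truncated-normal single-site sweeps (two per iteration);
2. person traits `eta` — conjugate MVN; the posterior precision
   `Phi^-1 + diag(sum lambda^2/psi^2)` is shared by all persons, so one
   Cholesky factorization serves the whole sample;
3. loading magnitudes — per-item random-walk Metropolis (the constraint
   `psi^2 = 1 - lambda^2` breaks conjugacy), with proposal scales adapted
   during warmup toward a 0.44 acceptance rate, plus two interweaving
   moves along weakly identified directions: an ancillary per-item update
   that holds standardized residuals fixed, and a per-trait scale move
   (`lambda_a -> r lambda_a`, `eta_a -> eta_a / r`) whose Metropolis ratio
   involves only the error variances, the priors and the Jacobian;
4. item means — conjugate normal, plus an exact Gaussian recentering of
   each block's common utility level (rankings identify only within-block
   differences, so the block location is a slow direction for single-site
   updates);
5. trait correlations — an inverse-Wishart covariance draw conditional on
   `eta` (prior df `T + 2`, identity scale), projected to a correlation
   matrix. This parameter-expansion-style projection is a pragmatic
   approximation to an exactly marginally-uniform correlation prior; it is
   weakly informative and standard practice in augmented probit samplers.

Estimation-side conventions mirror the generative ones: standardized
loadings with `psi^2 = 1 - lambda^2`, loading magnitudes restricted to
(0.05, 0.95) — the generative support, which also keeps the sampler away
from the degenerate `psi^2 -> 0` corner — and loading *signs* fixed to the
design keying, which resolves the reflection invariance deterministically.
Because the augmented utilities share one error per person x item, the
residual dependency between comparisons involving the same item is
represented exactly rather than through extra item factors.

Priors: half-normal(1) on loading magnitudes (truncated to the support),
N(0, 1) on item means (equivalently, a weakly informative prior on the pair
intercepts), and the near-uniform correlation prior induced by the
inverse-Wishart projection.

**EAP scores.** Trait estimates are posterior means of `eta`. The package
stores, alongside the raw draws, the *conditional* posterior mean of `eta`
given the augmented utilities at each iteration; averaging these
Rao-Blackwellized draws gives the same EAP with a much smaller Monte-Carlo
error, which matters for small models where the posterior is wide.

**Convergence.** Split-Rhat (each chain halved) is computed for `eta`,
loadings, item means and the free correlations; a fit with max Rhat above
the threshold (default 1.05) is *flagged*, never silently accepted, and the
flag propagates to EAP scores and result rows. Mixing is honest but not
free: data augmentation leaves long memory in the loadings (the utilities
carry the previous loading's imprint), so desk-scale budgets often land at
Rhat 1.1–1.3 on loadings even when EAP scores, loading recovery
(correlation with truth ~0.99 at N=300–500) and correlation-bias estimates
are already stable. The default budget is 4 chains x (1000 warmup + 1000
kept); desk-scale presets use 2 chains with longer warmup (the equally
keyed, realistic-loading regime needs ~2000+ warmup iterations for the
correlation matrix to settle, because ipsativity leaves `Phi` weakly
identified there).

## Recovery measures

* **Reliability**: squared Pearson correlation of estimated with true trait
  scores, computed per trait, then averaged over traits (and replications).
  The per-trait-then-average convention is the simplest one consistent with
  a per-trait definition; aggregation order is a package choice.
* **RMSE**: root mean squared deviation on the z-scale, pooled over persons
  x traits per replication, then averaged.
* **Intertrait-correlation bias**: estimated minus true correlation per
  unique trait pair, summarized as the *signed* mean. For classical scores
  the estimate is the Pearson correlation matrix of the score columns; for
  T-IRT it is the posterior mean of `Phi`. Fully ipsative scores on
  uncorrelated traits show the characteristic `-1/(T-1)` compound-negative
  structure.
* **Person-mean correlation**: correlation between each person's mean
  estimated and mean true trait — the direct ipsativity diagnostic. When
  either side's person means have zero variance (always the case for
  equally keyed classical scores) the quantity is UNDEFINED: it is stored
  as a first-class missing value, never as 0; only display layers may remap
  it.
* **Approximate CIs**: mean +- 1.96 x SD / sqrt(k) over the k replications
  of a condition (sample SD); undefined for k < 2.

Two analytic consequences connect RMSE to individual assessment: treating
estimation errors as N(0, RMSE^2), an individual's 95% interval has
half-width 1.96 x RMSE on the z-scale (0.67 -> +-1.31), and the interval
+-1.96 x RMSE covers `2 Phi(1.96 x RMSE) - 1` of a standard-normal
population (0.46 -> 63%).

## Study grid and reproducibility

The full factorial grid crosses scoring (2) x traits {5..30 step 5} x
N {100, 300, 500, 1000} x keying (2) x loading regime (2) x correlation
structure (2) = 384 conditions, 12 replications each (six correlation
submatrices, each used twice). Scoring is a post-hoc factor: the
replication seed is derived (via `numpy.random.SeedSequence`) from the
master seed, the index of the *non-scoring* factor cell, and the
replication number, so the classical and T-IRT cells of a matched condition
score the same simulated responses, and any replication is re-runnable in
isolation from its logged child seed with bit-identical data. Replications
are independent units; execution order cannot affect results.

Designs (loadings, blocks, intercepts) are redrawn per replication rather
than held fixed within a condition — a choice the package makes explicit
because it matters for exact numerical comparisons with other
implementations of the same study design.

## Desk-scale presets and what they show

Full-grid T-IRT runs at 30 traits and N=1000 need cluster-scale MCMC
budgets (days per model). The shipped desk-scale preset (5 traits, N=300,
zero intercorrelations, 2 Gibbs chains with ~2500 warmup iterations)
reproduces the study's *directional* structure on a workstation:

* T-IRT mean reliability >= classical mean reliability on matched
  responses — though at 5 traits the two methods are at their closest, so
  the gap is small (a few hundredths) and its replicate-to-replicate noise
  is of the same order;
* high-uniform loadings give materially higher reliability than realistic
  truncated-normal loadings (the strongest factor);
* mixed keying gives near-zero intertrait-correlation bias while equal
  keying leaves the characteristic negative bias — the partial-ipsativity
  signature.

Full-scale reference values (classical RMSE 0.67 and T-IRT RMSE 0.46 in the
most favourable realistic equally keyed condition at 30 traits, N=1000;
reliability >= .8 only with high loadings) are retained as machine-readable
targets (`tirtsim.runner.FULL_SCALE_TARGETS`) flagged `desk_scale=False`,
with the constraints required to reach them (the external empirical
correlation matrix and a cluster-scale MCMC budget) stated.

## What the synthetic data do and do not emulate

The generator implements the Thurstonian response process exactly, so
passing tests establish internal correctness of simulation, scoring and
estimation — not the behaviour of human respondents. Real FC data add, at
least: response processes that deviate from the Law of Comparative
Judgement (especially under cognitive load or faking incentives),
non-normal trait distributions, item-desirability confounds, and
questionnaires whose loadings and intercepts are not drawn from tidy
distributions. The `neo_like` correlation matrix is a synthetic surrogate
that mimics the hierarchical *structure* of a real inventory's facet
intercorrelations, not its empirical values; conclusions that depend on the
exact correlation pattern require supplying the empirical matrix via
`matrix_file`.

## Numerical notes and limitations

* Utility ties are measure-zero under the continuous error model; the
  simulator breaks any exact tie toward the lower item index so a fixed
  seed regenerates data bit-identically.
* Truncated-normal draws use inverse-CDF sampling with probabilities
  clipped to [1e-12, 1 - 1e-12]; the nearest-correlation projection adds a
  ridge of ~1e-8 where needed to keep matrices strictly positive definite.
* The grid-quadrature EAP reference integrates the exact ranking likelihood
  (probit for 2-item blocks; a bivariate-normal orthant probability with
  covariance induced by the shared middle-item error for triplets) on a
  regular grid over [-5, 5] at step 0.05; it is limited to at most two
  traits and is intended as a micro-scale reference, not an estimator.
* Classical zero-variance score columns are z-scored to zeros with a
  warning; they carry no ordering information.
* Gibbs mixing on loadings is the budget bottleneck (see Convergence);
  results that hinge on loading *uncertainty* (rather than point recovery)
  need larger budgets than the desk-scale presets.
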