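# Methods

## The score engine

An order-2 local scoring rule generated by a convex α: ℝ → ℝ is

    S(q, q′, q″) = d/dx α′(u) − α(u) + u α′(u),   u = q′/q,

with the total derivative expanded analytically by the chain rule,
d/dx α′(u) = α″(u)·u′ and u′ = q″/q − u².  This requires only (q, q′, q″)
at the evaluation point and involves no step-size choices; finite
differences are used only as oracles in tests and in the fallback path of
`score_from_f` (centered differences, step 1e-5·|x| for first partials,
1e-4·|x| for direct second differences — nesting two first differences
loses about three digits and is avoided).

Equivalently a rule can be given through a 1-homogeneous f(q, q′) with
S = −∂f/∂q + d/dx ∂f/∂q′; the two constructions are linked by
f(u, v) = u·α(v/u) and agree numerically to the accuracy of the finite
differences.  Homogeneity is validated by scaling checks (λ ∈ {0.5, 2,
3.7}, tolerance 1e-8) because the variational derivation presumes it.

Domain handling: under α(u) = u⁻², the argument u = q′/q must be nonzero.
Points with q′ = 0 (e.g. the mode of a symmetric density) are hard domain
errors in `score_from_alpha` and are excluded, with a logged warning, by
the grid scanner `verify_zero_score`.  This matches the intended use — the
prior candidates are decreasing densities on (0, ∞), where q′ < 0
everywhere.

The order-2 Euler–Lagrange residual
S + q ∂S/∂q − d/dx(q ∂S/∂q′) + d²/dx²(q ∂S/∂q″) is computed term by term
(third/fourth derivatives of α by centered differences, q‴ supplied by the
caller).  For every rule of this family the non-S part cancels
identically — that cancellation is the properness identity — so the
stationarity equation of the information criterion reduces to S = 0.
The tests verify both the reduction (residual = S to ~1e-5) and that the
heavy-tailed family a/(a+x)² sits in the zero set of the u⁻² rule at
machine precision.

## The priors

Positive axis: q(x) = a/(a+x)², a Lomax density with scale a and shape 1
— proper, decreasing, tail a/x², no finite mean.  Closed forms:
cdf x/(a+x), quantile a·p/(1−p), inverse-cdf sampling.  Real line:
q(x) = ½·a/(|x|+a)², sampled as a positive-axis magnitude with an
independent fair sign.  The scale constant defaults to a = 1 because the
positive-axis prior is invariant under φ = 1/x exactly at a = 1 (the
pushforward is a/(aφ+1)²); no data-dependent choice of a is offered.

Jeffreys' scale prior 1/σ and the flat location prior are carried only as
unnormalised log-kernels flagged improper; they can enter posterior
kernels for the comparison studies but cannot be sampled from.

## Samplers

All chains are driven by seeded `numpy.random.Generator`s; there is no
global RNG state.  Retention follows floor((n_iter − burn_in)/thin).
Proposal standard deviations are pilot-tuned during burn-in (every 50
iterations, scale ×0.7 if the window acceptance rate is below 0.2, ×1.4
if above 0.5) and frozen afterwards, so the retained draws come from a
fixed-kernel Metropolis chain.

*Scalar models.*  The normal-scale posterior (data N(0, σ²), priors
Jeffreys or score) and the log-normal location posterior (known unit
log-scale, priors flat or score) use sufficient statistics (Σx², Σlog x)
and a raw-scale random walk with off-support proposals rejected.

*Gaussian mixtures.*  Metropolis-within-Gibbs: (i) latent allocations by
Gumbel-max over component log-densities; (ii) conjugate
Dirichlet(1 + counts) weight update under the symmetric unit-concentration
prior; (iii) componentwise random walks for μ_l (real-line score prior)
and σ_l (positive-axis score prior), evaluated through per-component
(count, sum, sum of squares), so a sweep is O(nk).  Initialisation is
moment-based (means at interior quantiles of the data).  Label switching
is resolved after sampling by one global permutation — ascending
posterior-mean location for recovery studies, descending weight for
reporting observed-data fits; per-draw relabeling is deliberately not
used.

*Hierarchical model.*  y_j ∼ N(μ + α_j, se_j²) with known per-group
standard errors, α_j ∼ N(0, σ_α²), flat prior on μ.  μ and the α_j have
conjugate normal Gibbs updates.  σ_α² is drawn exactly from its
inverse-gamma conditional when the prior is IG(ε, ε), and by a random
walk on log σ_α² (with the e^t Jacobian) under the score prior, because
that posterior spans several orders of magnitude and raw-scale walks mix
poorly near zero.

## Studies and their scales

Table cells pair each prior with the same replicate datasets, and run one
Metropolis chain per replicate in lockstep as a numpy ensemble (identical
algorithm to the scalar sampler; per-chain adaptation).  Cell seeds
derive from SeedSequence keys (study seed, study code, cell coordinates),
so any cell is reproducible in isolation and reruns are bit-identical.

Error metrics: the scale study reports root-MSE of the posterior-mean
estimator divided by the true σ; the location study also records the
un-normalised MSE, which is both the only option at μ = 0 and the scale
on which the location results are conventionally read (it is ≈ 1/n,
constant in μ).  Intervals are equal-tailed from linear-interpolated
empirical quantiles — order-statistic reproducible, unlike HPD.

Default study conditions are 250 replicates, sample sizes {30, 100},
σ ∈ {0.25, 0.5, 1, 2, 5, 10, 20}, μ ∈ {0, 1, 5, 10, 50, 100}, chains of
6000 iterations with burn-in 1000 and thinning 10.  The mixture studies
use the three-component benchmark 0.25 N(0, 1.2²) + 0.65 N(−10, 1) +
0.10 N(7, 0.8²) at n = 200 with 60,000/10,000/100 chains, and equal-weight
k = 3, 4, 5 truths at n ∈ {50, 100, 200}; the test suite runs the
repeated-sampling variant at M = 5 replicates with 6000/1000/10 chains,
which is sufficient to resolve the qualitative spread ordering (smaller
with n, larger with k).  The hierarchical comparison uses
40,000/20,000/10 chains.

DIC follows the plug-in definition DIC = D̄ + p_D, p_D = D̄ − D(θ̄), with
θ̄ the per-parameter posterior mean after relabeling by descending weight.
A caveat discovered in validation: when a fitted mixture has more
components than the data support, the empty components' parameters wander
over the prior, θ̄ becomes a poor plug-in and p_D can go strongly
negative, making DIC drift downward with k.  The plug-in definition is
kept (it is the canonical one), but the synthetic model-selection checks
compare underfitted against correctly sized mixtures, where every
component keeps data.  Scans over observed data (e.g. the 82 galaxy
velocities, supplied as a plain-text file and not bundled) use the same
machinery via `scoreprior dic-scan`.

## What the generators do and do not emulate

The synthetic models match the study designs exactly (normal scale,
log-normal location, well-separated Gaussian mixtures), which is what the
frequentist-coverage claims are about.  They do not probe misspecified
likelihoods, overlapping mixture components, or small-J hierarchies
beyond J = 8, so passing tests say nothing about robustness in those
directions.

## Numerical choices and known limitations

* Coverage comparisons between two finite-replicate estimates carry the
  binomial noise of both sides; the tests propagate both (and also check
  against exact quadrature-derived coverages, 0.9488 for the σ = 2/n = 30
  scale cell and 0.9449 for the μ = 1/n = 30 location cell).
* The posterior mean of the between-school variance under the score prior
  is a heavy-tailed functional: its exact value by 1-D quadrature (group
  effects marginalised analytically) is 3.378, while single 40k-chain
  estimates vary with sd ≈ 0.47 across seeds.  Comparisons therefore use
  pooled chains and replication-error bands.
* Degenerate inputs: empty data, non-positive log-normal data, k > n,
  J < 2, truth = 0 in the normalised error, and p = 1 quantiles are all
  rejected with explicit errors rather than propagated as NaN/inf.
* Quantile-based intervals from 500 retained draws wobble by a point or
  two of coverage; the stated chain schedules are part of the study
  conditions and are not lengthened to hide this.
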