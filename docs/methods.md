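# Methods

## Demographic model

The life cycle is collapsed to three stages — 1st/2nd instar, 3rd instar,
and 4th/5th instar plus winged adults (the last two observed classes are
merged on input).  Daily dynamics follow the 3×3 Lefkovitch matrix with
survival σ, stage advance γ and per-capita reproduction φ; individuals can
advance at most one stage per day, and newborns are produced at rate φ per
stage-3 individual (the matrix's top-right entry is φ, not σφ).  The
asymptotic growth rate λ is the dominant eigenvalue.

Each vital rate is a linear function of covariates on its link scale
(logit for σ and γ, log for φ): an intercept, a density slope, six
treatment indicators and six caging×treatment indicators — 14 coefficients
per rate, 42 in all.  The treatment coding is deliberately redundant
(intercept plus an indicator for *every* treatment); identification of the
individual coefficients comes from the proper priors, while all quantities
entering the likelihood depend only on identified sums.  Density is the
total count divided by the leaf count (plant-size proxy).  By default the
density covariate is z-scored (the scaling is stored with the coefficients
and `CoefficientSet.to_raw()` converts back); raw-scale fitting is
available via configuration.  The caging dummy is 1 only on days ≥ the
cage-removal day (13) for uncaged-arm populations: those populations are
caged until removal.

Projection between censuses restarts from the observed stage vector and
steps one day at a time, recomputing density from the *projected* abundance
and that day's interpolated leaf count, and rebuilding the matrix daily.
Projected abundances remain real-valued; rounding happens only at
reporting.

## Plant-size interpolation

Leaf counts are observed only on census days.  Daily series are produced by
a penalized cubic smoothing spline with GCV-selected penalty (a generic
smoother in the role a per-plant GAM would play); fewer than five
observations degrade to linear interpolation and a single observation to a
constant.  Outside the observed range the boundary value is held, and the
series is clamped below at one leaf so densities stay finite.

## Likelihood and priors

For each consecutive census pair the projected stage vector `n̂` yields a
multinomial term for the observed end-of-interval stage counts (size = the
*observed* end total, probabilities `n̂/Σn̂`) and a Poisson term for the
observed total (mean `Σn̂`).  The printed form of the structure likelihood
draws "observed proportions"; a multinomial needs integer counts, so the
end-of-interval counts with the observed total as size is the well-defined
reading (and the standard construction in this literature).  An observed
count in a stage with zero projected probability gives −∞, not an error.

Clip-cage life tables (individuals at density 1 per leaf, caged) contribute
exponential lifespan terms at rate 1−σ(D=1), Poisson terms for daily
offspring counts at φ(D=1), and gamma terms for maturation ages.  The gamma
mean is constrained to the conditional mean first passage time 1+2/γ(D=1)
with only the shape k estimated (prior on ln k; estimating shape and rate
freely would cut the link between the maturation data and γ, so the
mean-constrained form is used).  σ, γ, φ at D=1 are computed per pure-clone
treatment and averaged on the response scale — the pooled life table
deliberately carries no clone information, leaving clone contrasts to the
census data.  Population-level and individual-level terms enter the total
unweighted.

Priors: independent Normal(mean 0, variance 10) on all 42 coefficients and
on ln k.

## Posterior sampling

The 43-dimensional posterior is sampled by Hamiltonian Monte Carlo:

* **Gradient** — a hand-derived reverse-mode (adjoint) pass through the
  daily projection, including the density-feedback term (each day's rates
  depend on the projected abundance).  The multinomial+Poisson pair
  simplifies: their log-total terms cancel, so ∂loglik/∂n̂ᵢⱼ = obsᵢⱼ/n̂ᵢⱼ − 1.
  The gradient is verified against central finite differences in the test
  suite.
* **Preconditioning** — the MAP (L-BFGS with the analytic gradient) and a
  finite-difference Hessian of the gradient give a Laplace covariance whose
  inverse serves as the HMC mass matrix.  Hessian eigenvalues are floored
  at half the prior precision: the prior contributes 1/10 curvature in
  every direction, so smaller values are numerical noise.
* **Step size** — dual averaging toward a 0.8 acceptance statistic during
  burn-in (then frozen); trajectory lengths are jittered uniformly over
  8–20 leapfrog steps.  Divergent trajectories (non-finite posterior) are
  rejected.
* **Ridge Gibbs** — the redundant treatment coding makes the likelihood
  exactly invariant under b₀ → b₀+δ, tᵢ → tᵢ−δ (per vital rate).  Along that
  line the conditional posterior is the prior restricted to it — Normal with
  mean (Σtᵢ−b₀)/7 and variance 10/7 — and is sampled exactly once per
  iteration, with the log-posterior and gradient updated in closed form.
* **Curved-valley block moves** — each treatment's three caging-effect
  coefficients trade off along a thin curved valley (different rate
  combinations produce near-identical dynamics), the slowest-mixing feature
  of this posterior.  Each such 3-D block gets an independence
  Metropolis-within-Gibbs update built to follow the valley: the widest
  block coordinate is drawn from a t mixture (fitted scale plus a wider
  tail-safety scale) and the other two from Gaussians centred on quadratic
  regressions against it, with their joint residual covariance supplying
  the off-curve noise.  Proposal parameters are fitted on a shared
  exploratory pre-run (a first HMC-only pass, then a second pass with
  provisional block moves enabled, refitting on the improved sample) and
  frozen before the production chains start, so the production kernel is a
  valid fixed Metropolis–Hastings update.  Every accepted block move
  decorrelates its valley completely.
* **Chains and diagnostics** — three chains by default, dispersed around
  the MAP (0.3× the Laplace scale).  A multi-start mode instead optimizes
  each chain's initial value from an independent 0.3-scaled prior draw and
  samples from the resulting basin: the inverse problem has genuine local
  optima, so restarts that land elsewhere make the chains disagree and the
  Gelman-Rubin gate flags it — the global-optimum verification.  The Gelman–Rubin statistic
  R̂ = √(((n−1)/n·W + B/n)/W) is computed per parameter with 1.05 as the
  flag threshold (flags are logged, not raised).  Runs are bit-reproducible
  given the seed; chain seeds are spawned deterministically.

Desk-scale defaults are 1,000 burn-in and 8,000 retained draws per chain
(the full field-study protocol of 50,000/50,000 remains available through
configuration).

### A note on identifiability

The inverse problem is intrinsically degenerate: many vital-rate
combinations produce nearly identical census dynamics.  Besides the exact
prior ridges removed by the Gibbs move, each treatment's three
caging-effect coefficients trade off along a thin *curved* ridge (higher
uncaged survival compensated by lower growth and reproduction), flattening
further where the logit saturates near σ ≈ 1.  These are the slowest
posterior directions; the HMC gradient is what makes them tractable at
desk scale, and in the full six-treatment crossing the most saturated of
them can still hover just above the R̂ = 1.05 gate in short runs.  The
bundled recovery study therefore uses a two-treatment design at full
replication, where the gate is met reliably; all 42 coefficients are still
estimated (absent-treatment coefficients are prior-dominated).

## Synthetic experiment

The generator reproduces the study design: 6 clonal treatments × 2 caging
arms × 8 replicates, 20 stage-2 individuals at day 0 (10+10 for mixtures),
censuses on days 0, 3, 7, 10, 14, 17, 21, 24, 28, 31, cage removal at day
13, individual-based daily dynamics (binomial survival, binomial advance of
survivors, Poisson births from the start-of-day stage-3 count), and
clip-cage life tables of 15/15/16 individuals for the pure clones
(geometric lifespans, 1 + two geometric(γ) waits to maturation recorded
only when reached before death, Poisson daily offspring).  One global seed
expands into deterministic per-population substreams.

True coefficients were chosen so caged response-scale rates at average
density span the realistic ranges for this system — survival 0.87–0.97
(increasing with density), stage advance 0.39–0.65 and reproduction
0.89–1.70 per day (both decreasing) — with cage removal pushing survival
toward 1 and depressing growth and reproduction.  Plants grow logistically
(6 → ~40 leaves, r = 0.15/day, lognormal per-plant variation, capacity
×0.35 after cage removal in the uncaged arm).  Densities then emerge in the
hundreds-to-thousands per leaf, matching the field scale.

Mixed treatments are simulated by default as two identically parameterised
lineages sharing the plant (using the mixture's own coefficient column), so
the generating process equals the inference model — making coefficient
recovery well-posed — while still producing genuine drift-driven clone
frequencies.  A `mixed_as_clones` mode instead runs the two *pure* clones'
coefficients against the shared density (frequency-weighted truth); the
transient-decomposition studies use it, passing the generator's true daily
frequencies as the reference regime.

What the generator does **not** emulate: counting error beyond the
likelihood's own observation model, winged-morph dispersal, predator
dynamics (caging acts only through coefficients and plant series), spatial
structure, and between-replicate heterogeneity in vital rates.  Passing
tests therefore demonstrate the estimator's correctness under its own
assumptions, not robustness to the extra noise real field data carry.

## LTRE decomposition

Profiles run over 200 (configurable) equally spaced densities from 0 to the
arm-specific 95% density quantile.  The reference is the response-scale
average of the relevant clones' rates at each density ("average clone" for
the three-clone contrast, 50:50 pair average for the evolution contrast);
each contribution is λ(reference with one rate replaced by the focal rate)
− λ(reference), computed at fixed density (no feedback of replaced rates on
density).  Equal rates give exactly zero contribution by construction.
Uncertainty bands are central 95% intervals over profiles recomputed for
1,000 (configurable) random posterior draws.

## Transient decomposition

For every observed structure of an evolving population inside the window
(caged: days 0–31; uncaged: days 17–31), the population is projected one
census interval ahead under the scenario ladder: reference
(evolving-treatment rates + own plant), step 2 (50:50 pure-clone rates +
day-specific mean plant of the pure-clone replicates in the same arm), step
3 (observed plant), step 4 (observed frequencies, linearly interpolated
between census days), step 5 (one vital rate at a time replaced by the
evolving-treatment rate, starting from step 4; replacing all three recovers
the reference exactly).  Census gaps of 4 days are projected over the true
gap and converted to daily rates with that gap.  Each scenario is scored by
1 − SSE/SST against the reference series — the proportion of variance in a
fixed target, which can be negative — rather than a squared correlation.

## Numerical choices and limitations

* Link inverses saturate (exp capped at e⁵⁰) instead of overflowing;
  saturated life-table rates (σ(D=1) → 1) yield −∞ likelihood, flagged not
  raised.
* Zero-start/zero-end census intervals are dropped at preparation (their
  contribution is parameter-independent).
* Interval observations with a zero observed start total are skipped in the
  transient analysis (daily growth undefined).
* Problem sizes in the test suite (two-treatment recovery design, 8,000
  retained draws, 20–50 seed replicates for Monte-Carlo checks) are the
  package's desk-scale defaults; the full-protocol settings are one config
  change away.
* The model shares one density slope per vital rate across treatments and
  assumes the same covariates act on all three rates; both are assumptions
  of the study design, not of this implementation.
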