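# aphidpop

Bayesian inverse demography for stage-structured aphid (*Myzus persicae*)
populations: estimate density-, clone- and caging-dependent daily vital
rates from interval census data plus individual life tables, then decompose
population-growth differences among clones and evolving (two-clone)
populations.

## The problem

Short-lived, small-bodied organisms cannot be followed individually inside
their populations, so their stage-specific survival, development and
reproduction must be inferred *inversely* from repeated censuses of
population size and stage structure.  This package implements that analysis
for a field experiment in which three aphid clones (A, B, C) and their
pairwise mixtures (AB, AC, BC) were grown on mustard plants, caged or
exposed (cages removed at day 13), censused every 3–4 days through day 31,
starting from 20 third-instar individuals per plant.

## The model

Three stages (1st/2nd instar; 3rd instar; 4th/5th instar + winged adults)
evolve daily through the Lefkovitch matrix

```
A = | σ(1−γ)   0      φ |
    | σγ     σ(1−γ)   0 |
    | 0       σγ      σ |
```

with vital rates linked to covariates by

```
ŷ = β₀ + β₁·D + β_{1+i}·Tᵢ + β_{7+i}·C·Tᵢ        (14 coefficients per rate)
σ = logit⁻¹(ŷ_σ),  γ = logit⁻¹(ŷ_γ),  φ = exp(ŷ_φ)
```

where `D` is density (aphids per leaf, plant size interpolated to daily
resolution), `Tᵢ` the aphid treatment (i = 1…6) and `C` a caging dummy.
Between censuses the matrix is rebuilt every day from the projected
abundance.  Observed stage counts enter a multinomial likelihood (size =
observed total, probabilities from the projection) and the observed total a
Poisson likelihood; clip-cage life tables add exponential (lifespan),
Poisson (daily fecundity) and gamma (maturation age, mean fixed at the
conditional mean first passage time `1 + 2/γ(D=1)`) terms.  Priors are
Normal(0, variance 10).  Sampling is by Hamiltonian Monte Carlo with an
analytic adjoint gradient; convergence is gated on Gelman–Rubin R̂ ≤ 1.05.

Downstream, LTRE (life table response experiment) decompositions attribute
differences in the dominant eigenvalue λ across a density grid to
one-at-a-time vital-rate replacements, and a five-step transient
decomposition quantifies how much of the evolving populations' 3-day growth
is explained by pure-clone demography, observed plant size, observed clone
frequencies, and single vital-rate substitutions.

## Worked example

```python
import aphidpop as ap

# a synthetic field experiment with known coefficients (2 treatments here)
ds = ap.gen_experiment(ap.ScenarioConfig(seed=1, replicates=8,
                                         treatments=("A", "B")))
fd = ap.dataset_from_synthetic(ds)

cfg = ap.MCMCConfig(chains=3, burnin=1000, draws=8000, seed=7)
chains = ap.run_mcmc(fd, cfg)
print(f"max R-hat  {chains.rhat.max():.4f}")
print(f"one-step predictive r^2  {ap.predictive_r2(chains, fd):.4f}")

grid = ap.density_grid(fd, arm="caged", n=50)
res = ap.ltre_clone_profile(chains.median_coeffs(), grid)
print(res.to_frame().head())
```

Output from this exact run:

```
max R-hat  1.0127
one-step predictive r^2  1.0000
      density  caged focal vital_rate  contribution
0    0.000000   True     A   survival     -0.007059
1   77.155649   True     A   survival     -0.006734
2  154.311298   True     A   survival     -0.006425
3  231.466946   True     A   survival     -0.006130
4  308.622595   True     A   survival     -0.005849
```

`max R-hat` close to 1 says the three chains agree on every one of the 43
posterior marginals; the predictive r² is the squared correlation between
observed and one-interval-ahead predicted stage counts (near 1 here because
the generating model and the fitted model coincide); each LTRE row gives
the change in asymptotic growth rate when the average clone's named vital
rate is replaced by the focal clone's, at the given density.

The same pipeline is available from the shell:

```
aphidpop all --seed 2 --out results/run2     # simulate → fit → diagnose →
                                             # LTRE → transient
```

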