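# hetdecay

Has a species been losing genetic diversity over the last century?  Museum
collections make the question answerable: specimens collected across decades
carry genotypes from which per-individual heterozygosity can be measured and
regressed on collection year.  Two things make the naive regression wrong for
this kind of data.  Specimens collected near each other are not independent
(spatial autocorrelation), and dried skins accumulate postmortem cytosine
deamination that surfaces as spurious C→T / G→A genotype calls, inflating
apparent heterozygosity in precisely the oldest samples.

`hetdecay` is a Python package for this analysis, built for population
geneticists working with probe-capture SNP data from natural-history
collections.  It provides:

- **Genotype QC for museum specimens** — the ordered cleaning chain:
  per-SNP genotyping-rate filter, removal of candidate deamination
  transitions using an outgroup ancestral-allele call, thinning to one site
  per contig, per-individual genotyping-rate filter, and a strict
  minor-allele-frequency filter; then per-individual heterozygosity.
- **The spatial decay model** — a Bayesian regression of heterozygosity on
  collection year with a Gaussian-process residual on geographic distance:

  H ~ MVN(μ, Σ), μᵢ = M + β·Tᵢ, Σᵢⱼ = α₀·exp(−α₁·Dᵢⱼ^α₂)

  with M the intercept, β the per-year effect, α₀ the sill, α₁ the decay
  rate and α₂ ∈ (0, 2) the powered-exponential shape.  Priors are standard
  normal (half-normal on the positive α's, uniform(0,2) on α₂); inference is
  MCMC with 4 chains, split-R̂/ESS diagnostics, and all estimates
  back-transformed to natural units.  The temporal effect is called
  significant when the equal-tailed 95% credible interval of β excludes
  zero.  A Poisson count-regression variant (log link, exposure offset,
  latent spatial field) checks robustness to heteroscedasticity and the
  bounded support of a ratio response.
- **Isolation by distance** — pairwise Weir–Cockerham (1984) FST between
  a-priori groups, linearization F/(1−F), and a one-tailed Mantel
  permutation test against geographic distance.
- **A synthetic-data generator** that emulates the study design end to end
  (spatially correlated heterozygosity fields with a linear time trend,
  genotype matrices realising target heterozygosities with injected damage
  sites, Balding–Nichols population structure at a target FST), so every
  stage is testable without any sequence data.

Models are exposed as sklearn-style estimators (`SpatialDecayModel`,
`PoissonDecayModel`, `QCPipeline`) with a functional API underneath, plus a
`hetdecay` command-line interface (`qc`, `fit`, `fit-poisson`, `ibd`,
`simulate`).

## Worked example

Fit the decay model to a synthetic dataset shaped like a century of museum
sampling (n = 50 specimens, 1902–2009, baseline heterozygosity 1.29 × 10⁻⁴
declining at −1.05 × 10⁻⁶ per year, spatially correlated residuals):

```python
import numpy as np
import hetdecay as hd

cfg = hd.SimConfig(seed=42)                       # study-shaped defaults
meta = hd.gen_metadata(cfg)
H = hd.simulate_het_field(meta, cfg.params, seed=43)

X = np.array([[m.longitude, m.latitude, m.year] for m in meta])
model = hd.SpatialDecayModel(n_iterations=10_000, thin=20, seed=0).fit(X, H)

s = model.summary_
print(s.table)
print(f"beta significant: {s.beta_significant}")
print(f"decline over {s.t_start:.0f}-{s.t_end:.0f}: {s.percent_decline_point:.1f}%")
print(f"max Rhat: {max(model.posterior_.rhat.values()):.3f}")
```

Output:

```
                mean        median        ci_low       ci_high
M       2.256075e-03  2.257948e-03  2.009369e-03  2.505225e-03
beta   -1.138046e-06 -1.137801e-06 -1.243626e-06 -1.033894e-06
alpha0  7.519161e-09  4.640772e-09  7.458106e-10  2.860112e-08
alpha1  9.489846e-04  2.327001e-04  1.093612e-05  6.427143e-03
alpha2  8.839811e-01  8.866407e-01  4.844716e-01  1.316338e+00
beta significant: True
decline over 1904-2006: 130.1%
max Rhat: 1.005
```

The posterior mean slope (−1.14 × 10⁻⁶ per year of heterozygosity, CI
entirely negative) recovers the generating value of −1.05 × 10⁻⁶, so the
temporal decline is flagged as significant.  The generating conditions imply
a near-total loss over the century, and because the Gaussian mean line is
not constrained to stay positive, the fitted line can cross zero inside the
sampling window — which is why the estimated percent decline here exceeds
100%.  (A slope of −1.05 × 10⁻⁶ per year from a baseline of 1.2915 × 10⁻⁴
corresponds to exactly an 87% decline over 107 years; `hd.percent_decline`
computes this directly.)  α₀–α₂ describe the spatial residual: the sill,
decay rate per km, and kernel shape.

## Layout

```
src/hetdecay/
  genotypes.py    GenotypeTable / SiteRecord / SampleMeta / HetRecord containers
  io.py           VCF (cyvcf2) and TSV readers/writers
  qc.py           cleaning chain + QCPipeline transformer + heterozygosity
  geo.py          haversine / euclidean-degrees distance matrices
  model.py        spatial decay regression: scaling, kernel, priors, MCMC,
                  back-transformation, summaries, SpatialDecayModel
  count_model.py  Poisson count-regression variant, PoissonDecayModel
  ibd.py          Weir-Cockerham FST, linearization, Mantel test
  simulate.py     study-shaped synthetic-data generators
  mcmc.py         adaptive Metropolis kernel, Rhat/ESS via arviz
  cli.py          click CLI
```

See `docs/methods.md` for the modelling details and design choices.
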