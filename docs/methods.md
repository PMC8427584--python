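# Methods

## The temporal decay model

Individual heterozygosity H_i (fraction of an individual's genotyped
positions called heterozygous; on the order of 10⁻⁴ when computed per
assembled base pair) is modelled as one realisation of a multivariate
normal:

    H ~ MVN(mu, Sigma),  mu_i = M + beta * T_i,
    Sigma_ij = alpha0 * exp(-alpha1 * D_ij^alpha2)

- **M** — global intercept, heterozygosity units.
- **beta** — per-year effect of collection year T_i on heterozygosity.
- **alpha0** — the sill: the residual variance, heterozygosity².  There is
  no nugget term; the diagonal of Sigma is exactly the sill (plus a purely
  numerical jitter of 1e-10·alpha0 for the Cholesky factorisation).
- **alpha1** — decay rate of covariance with distance, units
  distance^(-alpha2).
- **alpha2 ∈ (0, 2)** — powered-exponential shape.  The open interval is
  used: alpha2 = 0 degenerates to constant correlation and alpha2 = 2 (the
  Gaussian kernel) is the boundary of validity of the family, so both are
  excluded from the prior support.

This is a linear regression with spatially autocorrelated residuals — a
phenomenological description of diversity loss, not a demographic model.
The response is a ratio in [0, 1] while the Gaussian is unbounded; the model
is deliberately left untransformed and untruncated (the simpler
parameterisation), and the Poisson count variant (below) exists to check
that this mis-specification does not drive the conclusions.

An alternative kernel parameterisation alpha0·exp(-(alpha1·D)^alpha2) is a
pure reparameterisation (alpha1 ↔ alpha1^alpha2) that leaves beta and the
fit unchanged; this package standardises on the un-nested form above.

### Scaling and back-transformation

To condition the posterior for sampling, H is divided by its maximum, T is
shifted by its minimum and divided by its span, and D is divided by its
maximum.  The exact inverse map back to natural units is

    beta   = beta' * h_max / (t_max - t_min)
    M      = M' * h_max - beta * t_min
    alpha0 = alpha0' * h_max^2
    alpha1 = alpha1' / d_max^alpha2
    alpha2 = alpha2'

and is applied to every retained draw.  The round trip is an algebraic
identity (checked to 1e-12, with an absolute floor of a few ulps of the
cancelled beta·t_min term in the intercept).

### Priors

Standard normal on the scaled intercept and slope; standard normal
restricted to positives (half-normal, up to a constant) on alpha0 and
alpha1, since a variance and a decay rate are undefined at negative values;
uniform(0, 2) on alpha2.  These are weakly informative at the scaled-data
magnitudes.

### Sampling

Four independent chains of 10,000 iterations by default; the first half is
warm-up, and every 20th post-warm-up iteration is retained.  The kernel is
an adaptive random-walk Metropolis (Haario-style): the proposal covariance
is the running empirical covariance of the chain scaled by 2.38²/d, with a
Robbins–Monro-tuned global step size targeting ~30% acceptance.  Adaptation
happens only during warm-up; the retained draws come from a fixed, valid
kernel.  alpha0 and alpha1 are sampled on the log scale (with the Jacobian
included): their joint posterior forms a strongly curved ridge on the
natural scale and is far closer to Gaussian after the log map — this single
change moves split-R̂ from ~1.2–1.4 to <1.01 at default lengths.

Starting points are data-informed (the OLS line and its residual variance,
jittered per chain).  Convergence is operationalised — the package warns
when any split-R̂ exceeds 1.01 or any bulk ESS falls below 200 (arviz
implementations).  A fixed seed yields bit-identical draws; chains get
independent `SeedSequence`-spawned streams.

### Summaries and decisions

Equal-tailed 95% credible intervals; the temporal effect is "significant"
iff the interval for beta (natural scale) excludes zero.  The percent
decline over the sampled span is 100·(1 − (M + beta·t_end)/(M + beta·t_start)),
reported two ways: per draw (mean and CI, with draws whose baseline is
non-positive excluded and counted) and as a plug-in at the posterior means.
The plug-in is the stabler quantity: when the fitted line approaches zero
within the window the per-draw ratio blows up, and estimated declines near
or above 100% simply mean the (unbounded) mean line crosses zero.

A robustness refit drops all samples collected after a cutoff year
(`year_cutoff`, e.g. 1952), rescales and refits — guarding against leverage
from a handful of modern samples.

## The Poisson count variant

The count of heterozygous calls is modelled as Poisson with log link and
the number of genotyped positions as exposure offset:

    n_het_i ~ Poisson(lambda_i)
    log lambda_i = log n_genotyped_i + m + b*T'_i + u_i
    u ~ MVN(0, alpha0 * exp(-alpha1 * D'^alpha2))

Priors mirror the Gaussian model.  The latent field is non-centred
(u = L·z, z standard normal) and sampled by Metropolis-within-Gibbs: a joint
adaptive random-walk update of (m, b, alpha's) — which moves u implicitly
through L(alpha) — alternating with single-site random-walk sweeps over z
(per-site scales tuned to ~44% acceptance during warm-up only).  With the
field switched off and alpha0 → 0 the model reduces to ordinary Poisson
regression; the mode of (m, b) then matches IRLS, and multiplying all
exposures by c shifts m by −log c and leaves b unchanged.  This variant is
a sign/significance concordance check against the Gaussian model, not a
numerically interchangeable estimator; identifiability between m and the
mean of u is weak, so its intercept mixes slowly and only b-level summaries
(P(b < 0), CI sign) should be interpreted.

## Genotype QC

The cleaning chain, in order:

1. **Site call rate** ≥ 0.2 (inclusive).
2. **Damage transitions**: a site is removed when its allele pair is {C,T}
   with ancestral allele C, or {G,A} with ancestral G — i.e. the derived
   allele is the deamination product.  The rule keys on
   (ancestral, derived), not on which allele the VCF labels REF, because
   the damage process is strand-chemical, not file-orientation.  Sites with
   no ancestral call cannot be classified and are retained (counted as
   "unfilterable" in the report).
3. **One site per contig** — deterministic lowest-position by default
   (`random` with a seed available), removing within-contig linkage.
4. **Individual call rate** ≥ 0.4 (inclusive).
5. **MAF strictly > 0.01** — strict because the interest is in rare but
   real variants; a singleton in 50 diploids (MAF exactly 0.01) is removed.

The 20%/40% thresholds are read as minimum genotyping (call) rates; a
`rate_semantics="missingness"` switch flips them to maximum-missingness
bounds (the convention of the common command-line tools), since the two
readings differ and published wording is ambiguous.  Allele frequencies for
the MAF filter are computed from the samples present at that stage and are
not recomputed after the individual filter beyond the listed order.

Each filter is a projection (rows/columns subset), so the whole chain is
idempotent, and the per-stage report's counts are exactly the table
dimensions at each step.

Per-individual heterozygosity is n_het / n_genotyped.  The denominator
defaults to the genotyped sites present in the table; a `callable_totals`
mapping supplies per-sample totals of callable base pairs instead, which is
what produces the ~10⁻⁴ per-base-pair magnitudes when invariant assembled
positions are included.  SNP-table denominators and callable-base
denominators differ by orders of magnitude; the regression is invariant to
that choice up to rescaling, but reported magnitudes are not.

## Differentiation and isolation by distance

Pairwise FST between a-priori groups uses the Weir–Cockerham (1984)
variance-components estimator for biallelic loci, combined across loci as
the ratio of summed components (sum a / sum(a+b+c)); missing genotypes are
excluded per locus, loci lacking two genotyped diploids in either group are
dropped, and small negative estimates are passed through as usual.  Other
packaged estimators differ in small numerical details, so estimates here
need not match any particular program to the last digit.

Linearisation is F/(1−F) elementwise (undefined at F = 1).  Group locations
for the distance matrix are the centroids of member coordinates; the
default IBD metric is Euclidean distance on raw degrees (the great-circle
matrix is available).  The Mantel test correlates upper triangles
(Pearson), permutes rows and columns of one matrix jointly, and is
one-tailed upper — IBD predicts a positive correlation — with
p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm), so p ≥ 1/(n_perm+1); the default
is 9,999 permutations.

## Synthetic data

The generator defaults encode the study conditions: n = 50 individuals,
collection years uniform on 1902–2009, locations uniform in a ~2000 × 3000
km box over the Rocky-Mountain region (25° × 27° in degrees), baseline
heterozygosity 1.2915 × 10⁻⁴ at 1902 with slope −1.05 × 10⁻⁶ per year (the
pair that implies an 87% decline over 107 years), sill (2 × 10⁻⁵)², decay
range ~500 km, exponential shape (alpha2 = 1).

- `simulate_het_field` draws once from the MVN; draws below zero are
  truncated to zero (logged) purely so they can be realised as genotype
  frequencies — a deliberate generator-side deviation from the unbounded
  model.
- `simulate_genotype_table` realises target heterozygosities sitewise
  (het with probability h_i, otherwise hom-alt with a configured alt
  frequency), injects a chosen fraction of deamination-signature sites and
  returns their indices as ground truth, and adds missingness uniformly.
- `simulate_structured_populations` draws Balding–Nichols per-population
  allele frequencies (Beta around a uniform(0.1, 0.9) ancestral frequency,
  concentration (1−F)/F) and binomial diploid genotypes.

What the generator does *not* emulate: linkage disequilibrium within
contigs, coverage-dependent genotyping error and allelic dropout, the
empirical spatial clustering of museum sampling, temporal autocorrelation
of sampling effort, or sequence-level damage patterns (damage is injected
at the site level, not simulated through reads).  Passing the calibration
suites therefore certifies the estimator under the model's own assumptions
— correct likelihood, unbiased recovery, calibrated intervals — not
robustness to these real-data features.

## Calibration study sizes and numerical choices

The simulation suites use 100 replicates for slope-recovery bias, 200 for
interval coverage, 200 for the null false-positive rate, at 4 chains × 2,000
iterations with data-informed starts; 500 replicates × 999 permutations for
Mantel null calibration; 50 replicates of 2 × 20 diploids × 1,000 loci for
FST recovery.  Recovery/coverage data are generated with a decline over the
span equal to half the baseline (beta = −6.07 × 10⁻⁷/yr from 1.3 × 10⁻⁴),
a regime where the slope is well identified but not overwhelming.

Degenerate inputs are rejected loudly: constant collection years (slope
unidentifiable), empty analysis sets after filtering, zero-variance
distance triangles in the Mantel test, non-positive predicted baselines in
percent decline.  Cholesky failures raise with a suggestion to increase the
jitter rather than silently regularising.  The zero-sill limit of the MAP
line equals generalised least squares under the correlation kernel; it
coincides with ordinary least squares exactly when the kernel is
effectively diagonal, which is the regime used to verify it against the
closed form.

## Known limitations

- Heterozygosity is modelled unbounded; fits under near-total decline can
  put posterior mass on lines that cross zero (reported, not clamped).
- The decay-rate/sill pair (alpha1, alpha0) is weakly identified at n = 50;
  their marginals are broad and should not be over-interpreted.
- The Poisson variant's intercept is confounded with the latent-field mean;
  use it only for sign/significance of the trend.
- FST linearisation is undefined at fixation (F = 1); completely
  differentiated group pairs cannot enter the IBD regression.
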