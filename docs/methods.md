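# Methods

## Model

`bayesrs` fits the whole-genome regression

    y = mu 1 + W g + a + e

where `y` holds one pseudo-phenotype per reference animal (daughter trait
deviations or deregressed proofs in dairy applications), `W` is the
column-standardized genotype matrix, `g` the SNP allele-substitution
effects, `a` an optional residual polygenic term and `e` the residual.
With `X` the 0/1/2 dosage matrix (counting the second allele) and `p_j` the
second-allele frequency at marker j,

    w_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)),

the Hardy-Weinberg standardization, so each column has mean ~0 and variance
~1 when `p` comes from the same animals. Validation animals are standardized
with the *reference* population's frequencies — the effects were estimated on
that scale — and the choice is recorded in run metadata.

Each SNP effect follows a four-component normal mixture,

    g_j | k_j = c  ~  N(0, gamma_c * sigma_g2),
    gamma = (0, 0.0001, 0.001, 0.01),

with `sigma_g2 = r_y^2 * Var(y)` fixed (not sampled); `r_y^2` is the mean
reliability of the pseudo-phenotypes unless overridden. The mixture is a
computational device for mixing between null and non-null states, not a
biological hypothesis; ties among the non-zero scalers are permitted and
merge components (used by the test suite to reduce the model to a
two-component spike-and-slab).

BayesR places one genome-wide probability vector on the components with a
uniform Dirichlet(1,1,1,1) prior. BayesRS generalizes this: markers are
grouped into segments s (fixed-size windows) and each segment has its own
`pi_s ~ Dirichlet(alpha_s)`. BayesR is exactly the special case of a single
genome-spanning segment with `alpha = (1,1,1,1)`, and both run through one
code path, so the reduction is bit-exact at a shared seed.

Remaining priors are `a ~ N(0, A sigma_a2)` with `A` the pedigree-based
additive relationship matrix, `e ~ N(0, I sigma_e2)`, and flat priors on
`mu`, `sigma_e2`, `sigma_a2`.

## Gibbs sampler

Per sweep, in fixed map order (a permuted scan order is available for mixing
diagnostics): `mu`, then each marker, then `pi`, then the polygenic block,
then `sigma_e2`.

* **Marker update** (compiled kernel): indicator and effect are sampled
  jointly — the indicator from the effect-integrated conditional, then the
  effect given the indicator. With `c_j = w_j'w_j`,
  `rhs = w_j'e + c_j g_j` and `v_c = gamma_c sigma_g2`, component c > 0 has
  log weight

      log pi_sc - 0.5 log((c_j v_c + sigma_e2)/sigma_e2)
                + 0.5 rhs^2 v_c / (sigma_e2 (c_j v_c + sigma_e2))

  and component 0 has `log pi_s0`; a non-null effect is drawn from
  `N(rhs v_c / (c_j v_c + sigma_e2), sigma_e2 v_c / (c_j v_c + sigma_e2))`.
  These standard conjugate forms are guarded by a test that compares the
  sampler's marginal component probabilities against exhaustive enumeration
  of all indicator configurations on a 10x3 instance (effects integrated
  analytically), to 0.005 total variation.
* **Mixture proportions**: `pi_s ~ Dirichlet(alpha_s + n_s)` where `n_s,c`
  counts the markers of segment s currently in component c.
* **Polygenic block**: `a` is drawn jointly from its multivariate normal
  conditional with precision `I/sigma_e2 + A^{-1}/sigma_a2` via a dense
  Cholesky factorization; then `sigma_a2 ~ InvGamma(q/2 - 1, a'A^{-1}a/2)`.
* **Variances**: the flat-prior conditionals are improper-prior inverse
  gammas, `sigma_e2 ~ InvGamma(n/2 - 1, e'e/2)`; proper shapes require
  n > 4 (q > 4 for the polygenic block), which is enforced.

The residual `e = y - mu 1 - W g - a` is maintained incrementally and
recomputed from scratch every 100 sweeps; a drift above 1e-6 aborts the run.
Posterior means, per-marker component occupancy, per-segment occupancy
counts and segment variances accumulate over post-burn-in sweeps (default
thinning 1). Given identical inputs, configuration and seed, a run is
bit-reproducible, including all output files.

Reliability enters only through `sigma_g2`; residuals are homoscedastic.
This is a deliberate simplification — no per-record weighting is applied.

**Chain lengths.** Defaults are 20,000 sweeps with 10,000 burn-in, adequate
for references of a few thousand animals. Small references mix more slowly;
for them 100,000/50,000 is recommended, and `chain_stability` (mean pairwise
correlation of segment-variance profiles across repeated runs) is the
diagnostic to confirm a chosen length. Tests and the acceptance script use
shorter chains (400–4,000 sweeps) matched to their smaller problem sizes.

## Segment variances

Markers are partitioned into non-overlapping windows of fixed size (10 to
3,000 markers, or whole chromosomes) that never span a chromosome boundary;
a shorter remainder window closes each chromosome. For each post-burn-in
draw, the variance of segment s is the across-individual sample variance
(denominator n-1; the convention is recorded because the divisor is
otherwise arbitrary) of the partial genetic values `W_s g_s`; the estimate
is the posterior mean over draws. Reported proportions are of the *summed
posterior-mean segment variance*, and are labelled as such. Cross-population
comparison uses the Pearson correlation of two profiles on an identical
partition, with user-specified genomic intervals (e.g. a major-gene region
that would otherwise dominate) excluded by mapping them to segment indices.

## Prior transfer

After a source-population fit, the posterior mean count of markers per
segment in each mixture component (rows sum to the segment's marker count)
is extracted, multiplied by a scale factor, and used as `alpha_s` in the
target population. Because the counts sum to the marker count, an unscaled
prior weighs as much as the target data; the conventional scale sweep is
0.2, 0.4, 0.6, 0.8, 1.0, 1.25, 1.5. Zero counts occur (a component never
visited in a segment) and are floored at 1e-3 so the Dirichlet parameters
stay positive — negligible against segment sizes of 100 or more. The uniform
pseudo-count (1,1,1,1) is *not* added on top of scaled counts by default;
an `add_uniform` option exists for sensitivity analysis. Transfer requires
the identical marker panel in identical order in both populations
(`intersect_markers` first); alignment is verified id-by-id when the prior
carries its provenance, or on segment coordinates for priors loaded from
bare count files.

## Prediction and validation

The direct genomic value of validation animal k is
`DGV_k = mu_hat + w_k' g_hat + a_hat_k`. Default is the marker-only DGV
(`a_hat_k = 0`); a pedigree mode projects the reference polygenic estimates,
`a_val = A_vr A_rr^{-1} a_ref_hat`, for completeness. Accuracy is
`r(DGV, y)` over the validation animals. Two predictors validated on the
same animals are compared with the Hotelling-Williams t-test for dependent
correlations sharing one variable, on n-3 degrees of freedom, two-sided at
the 5% level; no multiple-testing correction is applied across traits or
segment sizes. The test's empirical type-I error is verified by simulation
to sit in [3.5%, 6.5%] at nominal 5%.

## Synthetic data generator

The generator emulates the study design the method assumes: a large source
population and a small target population (reference + held-out validation)
sharing QTL positions but differing in LD and allele frequencies.

* **Haplotypes**: two gametes per individual; along each chromosome a
  gamete's allele copies the previous marker's allele with probability
  `ld` (source default 0.7, target 0.5), otherwise draws fresh from
  Bernoulli(p_j); chains restart at chromosome boundaries. This first-order
  Markov model gives adjacent-allele correlation `ld` and geometric LD
  decay — controllable and seedable, unlike real block-structured LD.
* **Frequencies**: source frequencies uniform on [0.05, 0.5]; target
  frequencies are a bounded perturbation (±0.1) of them, emulating breed
  divergence.
* **Effects**: 20 QTL by default at random positions, components 3:1
  moderate (0.001 sigma_g2) to large (0.01 sigma_g2). At shared QTL the
  target effect is `rho_g g + sqrt(1 - rho_g^2) g'` with an independent
  same-component draw `g'` (default `rho_g = 0.9`); a disjoint mode gives
  the target its own independent QTL. The real-data occupancy pattern —
  thousands of markers with individually tiny effects — is not resolvable
  at desk-scale sample sizes, so the default architecture uses effects a
  small study can detect; this is a deliberate scaled-down design choice.
* **Phenotypes**: `y = u + a + e` with the marker term rescaled so
  `var(u)/var(y)` equals `h2_marker` (default 0.5) exactly, an iid polygenic
  term for `h2_polygenic` (default 0) and Gaussian residual; total variance
  ~1. The reliability column is set to `h2_marker + h2_polygenic`, which
  downstream anchors `sigma_g2`. The polygenic term uses an identity
  relationship matrix; pedigree-structured polygenic simulation is not
  provided.

Because the marker term is rescaled to hit `h2_marker`, true per-QTL effects
are larger than the fitted mixture's top component implies; the sampler
compensates by spreading effects over LD partners. Passing tests on this
generator therefore demonstrate ranking, transfer and calibration behaviour,
not that the mixture's variance scalers are correctly specified for real
traits.

## Numerical and design choices

* Complete-LD pruning compares each marker with the previously retained one
  and drops the later marker when the dosage r^2 is within 1e-12 of 1;
  dosage (not standardized) correlation is the conventional LD r^2.
  MAF filtering (threshold 0.01, strict less-than) precedes pruning;
  cross-population intersection comes last.
* A MAF threshold is compared against `min(p, 1-p)`; a marker at exactly the
  threshold is retained.
* The relationship matrix is built by the tabular method after a topological
  sort of the pedigree; cycles and self-ancestry are errors. A is inverted
  densely (desk scale); a 1e-8 ridge is added if the inverse fails.
* Chain initialization: `mu = mean(y)`, `g = 0`, `k = 0`, `pi` = normalized
  alpha, `sigma_e2 = Var(y)(1 - r_y^2)` floored at 1e-8, and
  `sigma_a2 = 0.05 Var(y)` when the polygenic term is on.
* Indicator counts transferred as priors are accumulated over post-burn-in
  sweeps only, consistent with their definition as posterior means.
* At small `n`, components 0 and 1 are nearly likelihood-equivalent
  (`c_j v_1 << sigma_e2`), so posterior mass moves freely between them; only
  their merged mass, and the variance-bearing components, are identified.
  Interpret `pi` posteriors accordingly.

## Problem sizes

The default synthetic study is 2,000 source animals, 400 target reference,
200 validation, 2,000 markers on 10 chromosomes, 20 QTL. The test suite and
the acceptance script run this design with chains of 1,000–4,000 sweeps and
10–20 replicates per experiment — sizes chosen so the full battery runs on a
single desk-class core while every experiment retains clear statistical
resolution.

## Known limitations

* No per-record weighting by reliability (homoscedastic residuals).
* Dense linear algebra throughout; panels beyond ~100k markers or ~10k
  animals would need blocked or out-of-core variants.
* The Markov haplotype model has no block LD, no mutation/selection, and
  the generator's two populations diverge only in frequency and LD strength.
* Transfer requires an identical marker panel; no lift-over or remapping.
* Heavier prior counts act partly as extra shrinkage: location-agnostic
  gains of order one accuracy point can appear even when the source's QTL
  are irrelevant to the target (see the disjoint-QTL arm of the acceptance
  experiment), so transfer benefits should be read against that baseline.
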