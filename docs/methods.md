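# Methods

## The enhancer-level association model

The region test is a summary-statistic *mean chi-square* ("SNP-wise mean")
model.  Each SNP's two-sided GWAS p-value is transformed to a 1-df
chi-square statistic `q_i`; the enhancer statistic is the mean of the `q_i`
of the SNPs falling inside the (optionally window-extended) enhancer.
Under the null hypothesis the vector of SNP Z-scores is multivariate normal
with correlation equal to the local LD matrix `R`, so `sum q_i` is
distributed as `sum_j lambda_j chi2_1(j)` with `lambda_j` the eigenvalues
of `R`.  The direction of SNP effects is not used (the unsigned transform),
matching standard practice for summary-statistic region tests.  A single
SNP reduces exactly to its own p-value; identity LD reduces to the central
chi-square with `m` degrees of freedom; perfect LD (rank-1 `R`) reduces to
the shared per-SNP p-value.  These identities are enforced to 1e-8 in the
tests.

`R` is the Pearson correlation of mean-imputed dosages from a reference
panel.  Monomorphic SNPs are dropped with a warning; SNPs absent from the
panel are dropped rather than assumed independent (counts logged);
eigenvalues are floored at `1e-8 * lambda_max` to guard near-singular LD.
Extreme p-values are clamped to `[1e-300, 1 - 1e-16]` before the probit
transform `z = Phi^{-1}(1 - p)`.

### Weighted chi-square survival function

`P(sum lambda_j chi2_1 >= x)` is computed by a branch of methods, each
validated against a Monte-Carlo oracle (MVN draws from `R`):

1. **Equal weights** (includes `m = 1` and rank-1 LD after dropping zero
   eigenvalues): exact central chi-square closed form.
2. **Ruben's series** (primary): the distribution as a mixture of central
   chi-squares with scale `beta = min lambda`.  All mixture coefficients
   are nonnegative and sum to one, so the truncation error is bounded by
   the missing coefficient mass (tolerance 1e-11, at most 1000 terms).
   Because the series expresses the survival function as a positive
   combination of chi-square tails, it retains *relative* accuracy deep in
   the tail.
3. **Imhof's integral** (when the Ruben series converges too slowly, i.e.
   very large eigenvalue spread): the Gil-Pelaez inversion, split at a
   finite point with the slowly-decaying oscillatory tail handed to
   QUADPACK's QAWF rule after factoring the integrand into
   `g(u) sin(phi(u)) cos(wu) - g(u) cos(phi(u)) sin(wu)` with `w = x/2`.
   Plain adaptive quadrature over the infinite oscillatory integrand does
   not reach the accuracy target; the oscillatory-weight rule does.
4. **Lugannani-Rice saddlepoint** where Imhof's absolute floor (~1e-8) is
   hit, preserving relative accuracy in the far tail; Liu's
   moment-matched noncentral chi-square as a last resort.

The accuracy target is 1e-10 absolute or 1e-4 relative, whichever is
looser.  The test suite checks 20 random LD matrices (dimension up to 10)
against a 100,000-draw Monte-Carlo oracle within three MC standard errors,
plus the closed-form identities above.

### Why 1 kb centroids

Variable-width regions suffer a length bias: in real GWAS the genome-wide
statistic distribution is inflated by polygenic background (lambda_GC of
large psychiatric GWAS is roughly 1.3–1.5), so regions containing more
SNPs accumulate more excess signal and longer regions get systematically
larger Z-scores even without any region-specific effect.  Normalizing
every merged region to a 1 kb window on its centroid equalizes the
expected SNP count and removes the dependence.  The generator exposes this
through `gwas_inflation` (default 1.0 = exact null; the length-bias study
uses 1.3): with variable-width regions (uniform 200–4000 bp) the Spearman
correlation of Z with region length is clearly positive, and after
centroid normalization it is statistically indistinguishable from zero.
The null-calibration study, by contrast, uses `gwas_inflation = 1.0`.

## The property layer

Property tests regress the enhancer probit Z on one covariate at a time
(marginal models), conditioned on technical confounders — by default
`n_snps` and `log n_snps`; enhancer length is constant 1 kb after centroid
normalization and is therefore omitted (configurable for non-normalized
runs).  Confounders that turn out constant or mutually collinear in a
given dataset are silently reduced to an independent basis (they carry no
information); a *tested covariate* collinear with the confounders is an
error, as is a zero-variance covariate.  Missing covariate cells cause
listwise deletion, with the used row count reported.  Continuous
covariates get a two-sided t-test; competitive set tests (binary
membership) are one-sided greater, asking whether member enhancers carry
more signal than the background.  Footprint covariates are additionally
conditioned on the total-binding-site column so that per-motif effects are
not proxies for overall footprint density.

An optional GLS mode whitens the regression with an
enhancer-by-enhancer correlation estimated from shared LD,
`corr(T_g, T_h) ≈ sum r^2(between) / sqrt(sum r^2(g) sum r^2(h))`; this
estimator is our own approximation, validated against the Monte-Carlo
correlation of simulated null statistics (within 0.05), and is off by
default.

Meta-analysis across annotations takes, per covariate, the result with the
largest |Z| and Bonferroni-adjusts its two-sided normal p for the number
of annotations combined (the reported statistic keeps its sign).  With
Z = 3.46 over 10 annotations this yields p_adj = 5.40e-3.  Multiple
testing across enhancers or motifs uses Bonferroni or Benjamini-Hochberg;
0.05 Bonferroni-corrected for a 388,011-region enhancer database gives the
genome-wide threshold 1.3e-7.  Group attributes (e.g. a TF annotation
versus motif AT content) are compared with the Wilcoxon rank-sum test,
exact for groups of at most 12 without ties, otherwise the tie-corrected
normal approximation.

## Intervals, covariates, overlap tests

Coordinates are 0-based half-open BED throughout; 1-based SNP/TSS
positions are converted on ingest.  "Falling within" an exclusion region
means >= 1 bp overlap (configurable to full containment).  Centroids use
the floor of `(start + end) / 2`; windows clipped at chromosome edges are
kept (and counted in the log) rather than shifted.  Merging preserves ids
of untouched intervals and re-ids fused groups.  Nearest distances use the
gap convention `other.start - interval.end` (0 for overlap or book-ended
contact); "within 5 kb" flags are boundary-inclusive.  AT fraction counts
A/T over A/C/G/T, case-insensitive, with N excluded from both numerator
and denominator; conservation means are taken over covered bases only
(zero-filling sparse constraint tracks would bias means toward 0), with a
configurable minimum-coverage threshold.  Motif AT content is the
probability-weighted mean of `p_A + p_T` over PFM positions, invariant
under reverse complement.  Footprints are assigned to an enhancer only
when fully contained in it and their quality score passes the cutoff
(default 55); one footprint annotated with several motifs counts once per
(footprint, motif) pair.

The overlap permutation test relocates the *enhancer* annotation (features
stay fixed; a flag flips this): each interval keeps its chromosome and
length and gets a uniform start among positions that avoid the exclusion
set, by rejection sampling capped at 10,000 attempts.  The empirical
p-value uses the add-one estimator `(1 + #{perm >= obs}) / (n_perm + 1)`
(`<=` for depletion) and can never be 0; the default permutation count is
1,000.  The permutation loop runs on flat arrays with the same placement
semantics as the public shuffle (verified by seed-determinism and
calibration tests).

Hi-C contact pairs map an enhancer to a gene when the enhancer overlaps
one anchor and the gene's **TSS** lies in the other (anchor order
irrelevant); promoters, not gene bodies, are taken as the contacted
element, with a body mode left as future work.  Gene sets become
competitive enhancer sets via "contacts at least one set gene".

## The synthetic-data generator

The generator emulates the full input stack with known ground truth:

- **Genotypes**: latent Gaussian AR(1) within LD blocks (default block
  2 kb, rho = 0.6), independent across blocks, thresholded at the MAF
  quantile (MAF ~ U(0.05, 0.5)) into haplotypes; dosages are haplotype
  sums over 500 reference samples by default.  Thresholding attenuates
  the latent correlation, so realized adjacent-SNP r is below rho.
- **Summary statistics**: per block, `Z ~ R delta + sqrt(inflation) *
  MVN(0, R)` with `R` the *panel-estimated* block LD and two-sided
  `p = 2 Phi(-|Z|)`.  The marginal (not joint) parameterization
  `mu = R delta` follows the summary-statistic generative convention.
- **Effects**: for a causal enhancer the per-SNP chi-square(1)
  noncentrality equals `beta * standardized covariate`, floored at zero
  (noncentrality is nonnegative; a signed delta would make the planted
  association quadratic rather than monotone in the covariate);
  `delta = sqrt(ncp)` at every SNP inside the enhancer.
- **Sequence**: per-enhancer per-base `P(A or T)` drawn from the
  configured range (default U(0.3, 0.7)), background 0.5.
- **Footprints, conservation, contacts**: Poisson counts per
  (enhancer, motif) with optional AT coupling; per-enhancer conservation
  means with run-level noise and optional coverage gaps; contact pairs in
  which causal enhancers preferentially touch risk-set genes.

Default sizes (2 chromosomes x 5 Mb, 2,000 enhancers of 1 kb, 5 SNPs/kb)
are the conditions of the calibration and recovery studies; the 50-seed
recovery study uses a 400-sample panel.  One RNG stream per artifact is
spawned from the master seed by fixed offsets, so regenerating one file
never perturbs the others.

What the generator does **not** emulate: realistic human LD maps and
recombination structure, allele-frequency-dependent effect sizes,
population stratification, genotyping error, and real enhancer length or
GC landscape.  Passing tests therefore demonstrate the *statistical
machinery* (calibration, power against planted effects, invariances), not
that any particular biological association would replicate.

## Numerical and design choices

- p-values clamped into `(0, 1]` on ingest; quantile transforms use
  `p >= 1e-300`.
- Enhancer state pooling happens before merging across adjacent differing
  states (the order is not dictated by the data model; pooling first keeps
  the merge a pure geometry operation).
- Average linkage on `1 - Jaccard` for annotation clustering; the cut
  level (number of groups) is a user parameter.
- Marginal, not joint, testing across motif covariates is the default; a
  joint mode can be composed from the same primitives.
- The reported property "Z" is the regression t statistic (equal to a
  normal Z for the sample sizes in question).
- Study sizes used by the validation script: 20 LD matrices x 1e5 MC
  draws; 2,000 enhancers for calibration; 1,500 variable-width regions
  for the length-bias study; 50 seeds x 2,000 enhancers for recovery;
  200 replicate overlap tests at 99 permutations.

## Known limitations

- The region model is the mean chi-square variant only; a top-SNP variant
  and individual-level-genotype PC regression are not implemented.
- GO-graph propagation is out of scope; gene sets are consumed as flat
  lists.
- The GLS enhancer-correlation correction is approximate and off by
  default.
- No liftover, BigBed/tabix indexing, or ChromHMM training; segmentations
  and footprints are inputs, not outputs.
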