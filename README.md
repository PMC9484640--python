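# rwas — regulome-wide association studies

`rwas` aggregates GWAS SNP summary statistics into **enhancer-level
association scores** in an LD-aware way, then tests quantitative and
categorical enhancer properties — AT richness, evolutionary conservation,
distance to the nearest TSS, HAR/HGE status, per-motif TF-footprint counts,
and Hi-C-defined gene-set contact — for association with trait risk.  It is
aimed at statistical geneticists and regulatory genomicists who have a GWAS
(e.g. schizophrenia), a chromatin-state enhancer annotation (e.g. pooled
ChromHMM enhancer states), and want region-level rather than gene-level
association signal.

## The model

For an enhancer with SNPs whose two-sided GWAS p-values are
`p_1, ..., p_m`, each p-value is converted to a 1-df chi-square statistic
`q_i = F^{-1}_{chi2(1)}(1 - p_i)` and the region statistic is the mean
`T = (1/m) sum q_i`.  Under the null the SNP Z-scores are multivariate
normal with correlation equal to the local LD matrix `R` (estimated from a
reference genotype panel), so

    sum_i q_i  ~  sum_j lambda_j chi2_1(j),      lambda_j = eigenvalues of R,

a weighted sum of independent 1-df chi-squares.  The survival function of
that weighted sum gives the enhancer p-value (computed exactly via Ruben's
chi-square mixture series, with Imhof integration and a saddlepoint for the
tails), and its probit transform `z = Phi^{-1}(1 - p)` becomes the response
of the property layer:

    z ~ intercept + covariate + confounders        (two-sided t-test)
    z ~ intercept + set membership + confounders   (one-sided, competitive)

with `n_snps` and `log n_snps` as default technical confounders, a
total-binding-site control for footprint covariates, max-|Z| meta-analysis
across annotations, and Bonferroni / Benjamini-Hochberg adjustment.

Enhancer annotations are prepared by pooling enhancer-like chromatin
states, merging adjacent intervals, **normalizing each merged region to a
1 kb window on its centroid** (which removes the length bias that plagues
variable-width region tests), and dropping regions that hit the MHC or the
ENCODE blacklist.  A blacklist-aware uniform shuffle provides empirical
observed-vs-expected overlap tests, and a synthetic-data generator emits
every input format with known ground truth.

## Worked example

```python
from rwas import SimConfig, simulate_study, run_region_assoc, PropertyModel
from rwas.covariates import at_fraction_table

cfg = SimConfig(n_enhancers=2000, effects={"at": 0.3})   # AT-linked risk
study = simulate_study(cfg, seed=7)

assoc = run_region_assoc(study.enhancers, study.gwas,
                         study.snp_locs, study.panel)
print(assoc.summary())

covs = at_fraction_table(study.enhancers, study.sequences)
print(PropertyModel(assoc, covs).fit().summary())
```

Output:

```
Enhancer association (SNP-wise mean chi-square model)
========================================================
enhancers tested      1984
enhancers dropped     16 (no usable SNPs)
SNPs dropped          0
median SNPs/enhancer  5.0
min p-value           7.66e-07
lambda (median chi2)  2.033

Enhancer property association (covariate mode)
================================================================
confounders: n_snps, log_n_snps  | test: two-sided

covariate                     beta        se       t           p       n
at                          3.9032    0.2184   17.87    2.49e-66    1984
```

The first block tests each 1 kb enhancer against the GWAS: 1,984 regions
had usable SNPs; the inflated median per-SNP chi-square (lambda ≈ 2)
reflects that this configuration plants signal in every above-average-AT
enhancer.  The second block regresses the enhancer probit Z-scores on the
measured AT fraction: the planted AT-risk association is recovered
decisively (t = 17.9).  On a null configuration (`effects={}`) the same
pipeline yields uniform enhancer p-values (lambda ≈ 1) and a
non-significant AT coefficient.

The same stages are available from the shell:

```bash
rwas simulate --out sim/ --seed 7
rwas prepare-enhancers --segmentation seg.bed --keep-states EnhA1,EnhA2 \
     --chrom-sizes chrom.sizes --exclude blacklist.bed --out enhancers.bed
rwas assoc --enhancers sim/enhancers.bed --gwas sim/gwas.tsv \
     --snp-loc sim/snp_loc.tsv --panel sim/panel.tsv --out assoc.tsv
rwas rwas --assoc assoc.tsv --covariates covariates.tsv --out rwas.tsv
rwas pipeline --config pipeline.yaml        # one-shot, writes a manifest
```

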