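# Methods

## The generative model

The synthetic cohort emulates a population-based height study with
familial substructure. Its default composition is 1304 adults — 565 men
and 739 women, 533 unrelated singletons and 771 relatives in 238 nuclear
families (two founder parents plus one or more offspring, distributed as
evenly as possible). Sexes are assigned so the cohort totals are exact
(fathers male, mothers female, remaining sexes randomized); ages are
uniform on 18–90 years. Pedigree age consistency (parents older than
offspring) is not enforced: no downstream statistic depends on it.

Genotypes are produced by gene dropping. Founder haplotypes carry
Bernoulli(p) alleles at each SNP, with allele frequencies uniform on
[0.05, 0.50] by default; offspring receive one haplotype from each parent
by a fair coin per SNP. SNPs are therefore independent and in
Hardy–Weinberg equilibrium among founders by construction, which keeps
every downstream oracle exact. An optional LD mode replaces the founder
draw with an AR(1) latent-Gaussian copula within consecutive blocks
(correlation `ld_rho`) and transmits whole blocks, producing the
multi-signal regional structure needed to exercise conditional analysis;
blocks remain independent of each other.

Height is

```
height = sex_mean(sex) + age_slope(sex) · (age − age_ref)
         + Σ_i β_i x_i (centered) + g_poly + e
```

with defaults `sex_mean` 177.7 cm (M) / 164.4 cm (F), `age_slope`
−0.195 (M) / −0.239 (F) cm/year (negative = decline with age,
`age_ref` = sample mean age), polygenic background variance 25 cm²,
environmental SD 4 cm. The polygenic deviate `g_poly` is drawn with
covariance `σ²_poly · A`, where `A` is the numerator relationship matrix
(2 × pedigree kinship, computed by the tabular method) and the draw uses
its Cholesky factor — exact at cohort scale (n ≈ 1300). Sex is encoded
0 = female, 1 = male everywhere.

Causal effects are drawn `β_i ~ N(1, h²_beta)` and rescaled so that the
additive score variance `Σ 2 p_i (1 − p_i) β_i²` is a chosen share of the
phenotypic variance net of age and sex (default 8% with 180 causal SNPs,
the regime where a transferred weighted score is informative but far from
deterministic). The positive mean makes most trait-increasing alleles
the counted allele, as in real panels, while `beta_heterogeneity`
controls how much effect sizes vary — the quantity that separates
weighted from unweighted scores.

External effect panels are emulated by perturbing the truth: reported
beta = true beta + N(0, est_se²), plus an optional fraction of entries
whose sign is forced opposite to the truth, mimicking the sign
discordance seen when small-cohort re-estimates are compared with
meta-analysis panels.

What the generator does **not** model: linkage disequilibrium beyond the
optional block copula, ascertainment, genotyping error, assortative
mating, population stratification, or shared-household environmental
correlation. Passing tests therefore demonstrate the estimators' behavior
under clean familial covariance and HWE — not robustness to confounding
or LD-induced redundancy in real panels.

## QC

Per-SNP filters with strict inequalities: MAF > 0.02, Hardy–Weinberg
exact-test P > 1e-4, call rate > 0.95, all computed on non-missing calls.
The HWE test is the exact conditional test (enumeration of heterozygote
counts given allele counts via the stable ratio recurrence, summing the
probabilities of all configurations no more probable than the observed
one, with a 1e-10 relative tolerance for ties). Missing dosages are a
distinct NaN sentinel, never conflated with dosage 0. Sample-level chip
QC is out of scope because it operates on array intensities. The call
rate filter is per-SNP.

## Scores

Panels align to the genotype matrix by snp_id, falling back to
chromosome+position only when the allele sets match (possibly after
strand complement). Strand-ambiguous (A/T, C/G) SNPs are dropped by
default since a silent strand error corrupts a score irreversibly; a
`keep` policy exists for panels known to share the strand convention.
Missing genotypes contribute their expectation (2 × cohort effect-allele
frequency for allele-count scores; the HWE-weighted mean of the class
weights for genotypic scores) so that n stays constant across panels.
Weights are used exactly as reported — `r²` is invariant to their scale,
so log-OR panels need no conversion. One caveat: reflecting a panel
(swapping alleles and negating betas) leaves unweighted and genotypic
scores exactly invariant but shifts the weighted sum by the constant
`−2 Σ β`; all variance-explained results are unaffected.

## Variance explained

Height is adjusted once, in the pooled sample, by OLS on age, sex and
age × sex; residuals are standardized (ddof = 1) and reused for every
analysis, including the sex strata — matching a design in which a single
covariate model serves all analyses. `r²` is the squared Pearson
correlation between residuals and score (two-step), not the incremental
`r²` of a joint covariate+score model; the two differ slightly because
scores are not exactly orthogonal to the covariates in-sample. Joint
`r²` for several scores is the multiple-regression `R²`; collinear
predictors are absorbed by a minimum-norm least-squares solve, so a
duplicated score adds exactly nothing.

## Association

The per-SNP scan regresses standardized residuals on dosage (with
intercept). Relatedness is handled two ways:

- **Genomic control**: `λ = median(χ²)/0.4549364`; statistics are divided
  by `max(λ, 1)` (λ is reported unclamped as the diagnostic), a monotone
  transform that preserves SNP ranking exactly. The median constant is
  fixed, not recomputed, for bit-stable results.
- **Measured genotype**: genomic kinship
  `K_jk = (1/M) Σ_m (x_jm − 2p_m)(x_km − 2p_m)/(2 p_m (1 − p_m))`
  from all SNPs with mean-imputed missing calls; null variance components
  by maximum likelihood (intercept-only fixed effects on standardized
  residuals makes ML the natural choice) via one eigendecomposition of
  `K + 1e-8·I` and a bounded 1-D search over the heritability ratio, with
  the total variance and GLS intercept profiled out analytically. The
  per-SNP test is then GLS under the fixed covariance — the standard
  two-step approximation to a full per-SNP mixed model, orders of
  magnitude faster and indistinguishable at these effect sizes. The
  per-SNP residual scale is re-estimated (weighted RSS/(n−2)), which
  makes the scan collapse *exactly* to OLS when `σ²_g = 0`.

When `K` is numerically indistinguishable from `I` the two components are
unidentifiable (only their sum is constrained); the fit is flagged
degenerate with the `σ²_g = 0` convention. Conditional re-analysis of a
region regresses residuals on each member SNP with the index SNP's dosage
as a covariate (OLS or GLS), skipping SNPs collinear with the index.

Attenuation caveat: because the genomic kinship is a noisy, sample-
centered estimate of the pedigree relationship, `σ²_g` is recovered with
a modest downward bias (~15–20% at 600 samples / 6000 SNPs) — the
familiar GRM-LMM behavior, within the accepted 30% recovery band.

## Regions, recovery, concordance

Regions grow outward from each seed SNP (p < 5e-4) over consecutive SNPs
in position order; a neighbor is absorbed iff its p < 5e-3 **and** its
distance from the current region edge is ≤ 25 kb — edge-relative
distance, the only reading that lets a chain of sub-25 kb steps span a
region many times larger than the cap. Overlapping spans merge; each
region's index SNP is its minimum-p member, and regions rank by index p.
Recovery against a locus catalog reports both criteria separately —
catalog SNP inside the region interval, and catalog SNP within an
inclusive 250 kb window of the index SNP — plus their union, since
published descriptions of such rules are often ambiguous between the two.
Chromosome labels are normalized (`chr2` = `2`).

Effect-size heterogeneity uses the two-sample z with a standard-normal
reference (reference SEs come from large meta-analyses, so no t
correction); multiple testing uses Bonferroni as the conservative
default, reported alongside nominal counts. Concordance re-orients panel
betas to the cohort's counted allele before correlating; zero products
count as concordant. Cohort betas for concordance are computed on
cm-scale residuals so both studies share phenotype units.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 350–1304 with 180–20,000 SNPs and
5–50 replicates per claim — sizes at which every check runs in seconds to
a couple of minutes while Monte-Carlo error stays well inside the
asserted tolerances. Calibration assertions use binomial 99% bounds at
the relevant SNP count. Fixed constants: 1-df chi-square median 0.4549364;
kinship ridge 1e-8; HWE tie tolerance 1e-10 relative; collinearity cutoff
|r| > 1 − 1e-10 for conditional covariates. p-values are clipped away
from exact 0 so `p ∈ (0, 1]` always holds.

## Known limitations

- No LD-aware clumping or re-weighting; the region rule is purely
  positional, as specified.
- The two-step MG test slightly underestimates per-SNP uncertainty
  relative to a full per-SNP REML mixed model when `σ²_g` is large and n
  is small.
- The generator's independence assumptions mean panel SNPs are never
  redundant proxies of each other, so score r² here is an upper bound on
  what identical settings would yield with correlated panels.
- The pipeline runs single-threaded and in memory; cohorts far beyond
  ~10⁴ samples × ~10⁵ SNPs would need chunked IO.
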