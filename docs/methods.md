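# Methods

`admixscan` tests for selection against admixture in a two-population hybrid
zone genotyped with reduced-representation sequencing, and links candidate
loci to fitness-proxy phenotypes measured repeatedly in a common garden. The
motivating system is a pair of weakly diverged conifer populations ("island"
and "mainland") with a cohort of first-generation (F1) hybrids, but nothing
in the code is tied to that system beyond the three ancestry labels.

## The heterozygosity-deficit test

At a biallelic SNP, a neutral F1 receives one gamete from each parental gene
pool. If the reference allele has frequency `p_I` in the island pool and
`p_M` in the mainland pool, an F1 is heterozygous with probability

    h = p_I (1 - p_M) + (1 - p_I) p_M

Selection against island x mainland heterozygotes — at any life stage from
pollination to survival in the garden — depresses the observed F1
heterozygosity `H_O` below `h`. The test:

1. estimates `p_I`, `p_M` by plug-in from non-missing parental genotypes;
2. simulates `B = 1000` cohorts of `n_F1` hybrids by gamete union; each
   cohort's `H_O` is an exact `Binomial(n_F1, h) / n_F1` draw, and the B
   draws form the locus's null distribution;
3. computes the lower-tail empirical p-value with the add-one rule
   `p = (1 + #{null <= observed}) / (B + 1)`, so p is never 0 and is floored
   at `1/(B+1)`;
4. applies Benjamini-Hochberg across all testable loci and calls candidates
   at FDR < 0.1.

Sampling error in the plug-in parental frequencies is deliberately not
propagated (the published procedure this mirrors does the same); with ~70
parents per population this inflates the nominal 5% tail to roughly 6.5%,
which the calibration tests document. Loci with no genotyped parents in
either population, or no genotyped F1s, are excluded from the scan and from
the BH denominator. Null streams are keyed on `(seed, crc32(locus_id))`, so
per-locus results are invariant to locus order and subsetting.

## Genomic clines

The hybrid index `h_i` of individual `i` is the maximum-likelihood mainland
ancestry proportion: genotypes are `Binomial(2, q(h))` with
`q(h) = h p_M + (1 - h) p_I`, maximized by bounded 1-D search (tolerance
1e-4). Parental individuals are included for anchoring.

The cline test compares, at one locus, the observed genotype-vs-`h`
relationship with the neutral gamete-union law: the alternative is a
multinomial logistic regression of the three genotype classes on `(h, h^2)`
(near-unpenalized), and the statistic is twice the log-likelihood gain over
the neutral law. Because that alternative only nests the neutral model
asymptotically, small negative statistics (> -1e-8) are clipped to zero.
Significance comes from parametric simulation: B cohorts are drawn from the
neutral law at the same `h` vector, the statistic is refit, and
`p = (1 + #{null >= observed}) / (B + 1)`. This is a documented variant of
tool-based cline "permutation" tests, not a numerical clone of any of them;
agreement with other tools should be assessed at the level of flagged loci.

## Diversity statistics

Nei-style estimators per locus and ancestry group: `H_O` is the heterozygote
fraction among non-missing genotypes; gene diversity uses the small-sample
correction `H_S = (2n/(2n-1)) (1 - p^2 - q^2 - H_O/(2n))`;
`F_IS = 1 - H_O/H_S` where `H_S > 0`. Per locus, `H_T` comes from the
unweighted mean of group frequencies and `F_ST = 1 - mean(H_S)/H_T`;
genome-wide summaries use ratio-of-sums. A locus is "fixed" in a group when
every non-missing genotype is the same homozygote class (a mixed 0/0 + 1/1
locus is polymorphic; the looser reading is available behind
`allow_mixed_homozygotes`). Fixed-count contrasts between groups use
Fisher's exact test (Monte-Carlo fixed-margins sampling for the 3x2 overall
table, exact hypergeometric for pairwise), BH-corrected. Group `H_O`
distributions are compared with Dunn's mid-rank z-tests with tie correction,
BH within each SNP set, and compact-letter displays at FDR < 0.1.

## Filtering

The VCF cascade mirrors standard ddRAD practice: genotypes with GQ < 20 or
DP < 3 are masked; sites are dropped in a fixed order (non-biallelic/indel;
QUAL <= 20; MAC < 3; MAF < 0.01; call rate < 0.8; mean depth > 23; any
ancestry group's F_IS outside [-0.5, +0.5]); individuals with > 50% missing
genotypes are removed. MAF/MAC/call rate are computed post-masking across
all individuals. Each site is charged to the first rule it violates, so the
per-rule report is reproducible; the surviving set does not depend on rule
order. The F_IS rule is a paralog-collapse guard, but note that a locus
under strong selection against heterozygotes in F1s legitimately has F1
F_IS near 1 — with the per-group rule such loci are removed before the scan
ever sees them. Both the bound and the per-group vs all-group behavior are
configurable for this reason, and the pipeline tests run with the bound
relaxed when selection signals are planted.

## Relatedness-aware association

* **GRM** — VanRaden centered cross-product `W'W / (2 sum p(1-p))` over
  polymorphic loci, with per-locus mean imputation of missing dosages.
  Sample centering pins the grand sum of the matrix near zero, so the
  off-diagonal mean is `-mean(diag)/(n-1)`, not 0.
* **PCA** — mean-imputed dosages, centered and unit-scaled, SVD; signs fixed
  by making each component's largest-magnitude loading positive.
* **Heritability** — REML of `y = Xb + g + e`, `cov(g) = s2_g K`, via one
  eigendecomposition of `Z K Z'` and 1-D profile optimization of the
  variance ratio (EMMA-style). `h2 = s2_g / (s2_g + s2_e)` with year and
  block as fixed covariates by default; SEs from a numerical observed
  information matrix.
* **Repeated-measures GWAS** — two-stage: a no-SNP mixed model with
  polygenic (GRM), permanent-environment, block and year random effects is
  fitted by average-information REML (step-halved, so the restricted
  likelihood trace is non-decreasing; variances floored at 1e-8 of the
  phenotypic variance); then each SNP is tested by GLS with that covariance
  fixed, Wald p-values, BH per trait, candidates at FDR < 0.1. Effects are
  per reference-allele copy. The permanent-environment variance is
  unidentifiable with a single record per individual and the fit refuses to
  run in that case.
* **Marginal means** — at a focal locus, a mixed model with genotype class
  as a fixed factor (cell-means coding), optional centered PC1/PC2
  covariates, and block/year/individual random effects. Adjusted means are
  the class coefficients on the reference grid; pairwise contrasts use
  Tukey adjustment via the studentized range with residual degrees of
  freedom (Bonferroni and unadjusted available); letters at adjusted
  p < 0.05. With no random terms and no PCs this reduces exactly to OLS
  cell means.

## Enrichment

Per term, a 2x2 table counts annotation *instances* (successes) against all
other instances (failures) in the candidate set versus a without-replacement
random background (default 500 loci, seeded). Fisher two-sided p-values are
BH-corrected within each annotation stratum (plant-ontology as one; gene
ontology split into biological process / molecular function / cellular
component); effects are Haldane-Anscombe log odds ratios (+0.5 per cell)
with SE, finite even with empty cells. Instance counting follows the
literal successes/failures definition; `unique_per_locus=True` switches the
unit to loci. Because failures are "all other instances", truly enriched
terms mechanically depress the remaining terms — directions are relative,
which is inherent to this competitive counting scheme.

## The synthetic-data generator

`synthio` emulates the study the analyses assume, with defaults fixed at the
study's shape: 11,379 biallelic SNPs; 68 island + 75 mainland + 66 F1
individuals; genome-wide Nei F_ST 0.0129; ancestral allele frequencies
uniform on (0.05, 0.95), i.e. mostly polymorphic post-MAF-filter loci; four
repeated-measures fitness proxies over eleven years in six blocks; 5%
uniform missingness (technical missingness is roughly uniform after
filtering); site QUAL 60, GQ 99, DP 15 so synthetic data pass the default
cascade untouched.

Divergence follows the Balding-Nichols model. For a requested two-deme Nei
F_ST of `t`, frequencies are drawn at BN parameter `F = 2t/(1+t)`: the
two-deme ratio-of-averages Nei F_ST of BN pairs concentrates around
`F/(2-F)`, so drawing at `F = t` would realize only about `t/2`. Ancestral
frequencies of exactly 0 or 1 are absorbing; a target of exactly 0
degenerates the Beta and falls back to identical frequencies with a warning.

Parental genotypes are HWE binomial draws by default. An optional
half-sib family mode (`n_families_*`) draws maternal trees in HWE and forms
each offspring from one maternal gamete plus one population pollen gamete —
the open-pollinated progeny-trial design common gardens actually have. The
family mode exists because marker-GRM REML on a few hundred *unrelated*
individuals is nearly unidentified (single-fit SD ~ 0.2 on h2); half-sib
relatedness contrast brings that to ~0.06, which is what the
parameter-recovery tests exercise.

F1s are island x mainland gamete unions. Selection against heterozygotes at
designated loci acts as multiplicative viability `(1-s)` per heterozygous
selected locus. Because loci assort independently, the survivor distribution
factorizes and is sampled exactly per locus (equivalent to rejection
sampling, which becomes computationally impossible when many loci are under
`s = 1`). Selected loci default to diagnostic-like frequencies
(p_I = 0.9, p_M = 0.1) so selection has heterozygotes to act on.

Phenotypes follow the generative mirror of the GWAS model:
`y = sum(beta_l d_l) + g + pe + block + year + eps` with
`g ~ N(0, s2_g GRM)`. Default variance components (0.3 / 0.1 / 0.05 / 0.05 /
0.5) give `h2 = s2_g/(s2_g + s2_p + s2_e) ~ 0.33`, inside the study's
reported 0.13-0.38 range. Annotations plant configurable-odds terms on
candidate loci over a baseline rate (default 0.08, odds ratio 8).

What the generator does **not** emulate: linkage disequilibrium (loci are
independent), non-uniform missingness, genotyping error, F2/backcross
cohorts, read-level data, and cytoplasmic inheritance (the study's
hybridization is unidirectional — island mothers — but organellar markers
are out of scope, so this is noted rather than modeled). Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed model, not robustness to LD or structured missingness in real data.

## Numerical choices and degenerate inputs

* Empirical p-values are add-one; BH excludes NaNs from the test count.
* The Yates correction term is `min(0.5, |O-E|)` so proportional tables give
  exactly 0; zero-margin tables are errors.
* r x 2 Fisher tables use 1e5 fixed-margins Monte-Carlo samples with the
  table-probability rule and the add-one p (seeded); 2x2 tables are exact.
* AI-REML starts from an equal split of the phenotypic variance; steps are
  halved until the restricted likelihood does not decrease; convergence is
  declared at a gradient norm below 1e-6 (relative) or when no uphill step
  exists. Non-PSD GRMs get a 1e-6 ridge.
* Bounded hybrid-index optimization uses tolerance 1e-4; likelihoods clip
  frequencies to [1e-9, 1 - 1e-9].
* Degenerate single-class genotype distributions in the cline test replace
  the regression with saturated class proportions and are flagged.

## Problem sizes in the test suite

The suite exercises the study-scale statistics at reduced problem sizes
chosen to keep the complete run within a few minutes while retaining
statistical resolution: calibration runs use 5,000-locus genomes, power runs
1,000 loci with 50 planted targets, variance-component recovery uses
n = 300 individuals (26 half-sib families, 2,000 loci) with 20 replicates,
and the GWAS checks use 500-SNP scans of 200 individuals over 5 years. The
exhaustive Fisher/Yates cross-validation enumerates every 2x2 table with
total count <= 30 against direct hypergeometric enumeration.
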