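# Methods

`tapa` tests the self-contained null hypothesis of pathway association —
no SNP assigned to the pathway is associated with the outcome in any of
the L ancestry groups — using only per-ancestry GWAS summary statistics
(effect estimates, standard errors, p-values), per-ancestry reference
genotype panels, and a SNP-to-gene-to-pathway assignment.

## The resampling core (ARTP)

All strategies share one adaptive rank truncated product engine. For a
set of q component p-values p₀ = (p₀,₁,…,p₀,q) and truncation points
c₁ < … < c_K, the statistic at threshold c_k is the negative log
product of the c_k smallest p-values,

  w₀,k = −Σ_{i≤c_k} log p₀,(i).

M replicas of p₀ are generated under the global null; every statistic
(observed and replicate) is converted to an empirical p-value ξ by
tie-inclusive leave-self-out counting on the grid {0,…,M}/(M+1); the
minP statistic is T = min_k ξ_k; and T₀ is calibrated against the M
replicate minima by the same counting, yielding τ₀. Because the
replicate-level τ_m are computed alongside τ₀ (leave-self-out again),
they are valid null replicas of τ₀ and feed the next aggregation level
without any new sampling: one pool of M draws calibrates the whole
SNP → gene → pathway hierarchy.

Counting conventions worth noting: large w is significant (counts use
≥), small T/τ is significant (counts use ≤), and ties are always
included. Empirical p-values of exactly 0 are possible (numerator has
no +1); before any subsequent log transform they are floored to half a
grid step, 0.5/(M+1), which preserves ordering. Defaults: c = (1, 2)
at the SNP level; K′ = 10 gene-level thresholds d_k = k·max(1, ⌈J/20⌉)
capped at J; M = 10,000 for data analysis (the simulation profiles use
M = 1,000, which resolves the 0.05 and 0.01 levels comfortably).

## Null replicates from LD reference panels

Under the null, the z-score vector of a gene's SNPs in ancestry l is
approximately N(0, V⁽ˡ⁾) with V⁽ˡ⁾ the genotype correlation matrix of
those SNPs in population l. V⁽ˡ⁾ is estimated from the ancestry's
reference panel (pairwise-complete Pearson correlation of dosages;
panel-monomorphic SNPs are dropped from that ancestry), then repaired
to positive definiteness by adding ε to the diagonal — ε doubling from
1e-8 until a Cholesky factorization succeeds — and renormalizing the
diagonal to 1. Genes whose SNP sets overlap, or whose cross-gene SNP
correlation exceeds |r| > 0.1 in any ancestry, are clustered and drawn
jointly so cross-gene dependence propagates into the null.

For the IVW statistic the per-ancestry draws can be bypassed: the
combined statistics' null covariance is assembled directly as
cov(s_i, s_i′) = Σ_l ω_i⁽ˡ⁾ ω_i′⁽ˡ⁾ V⁽ˡ⁾_{ii′} and sampled once (the
default route for SNP-IVW; both routes are implemented and agree in
distribution, which the test suite checks).

## Trans-ancestry combination statistics

With z_i⁽ˡ⁾ = β̂_i⁽ˡ⁾/τ_i⁽ˡ⁾ and study weights ω_i⁽ˡ⁾ ∝ 1/τ_i⁽ˡ⁾
(normalized by Σ_l (1/τ_i⁽ˡ⁾)², zero where a study lacks the SNP):

* **IVW**: s = Σ_l ω z, null variance Σ ω²; optimal for a shared
  effect across ancestries.
* **max**: s = max_l |z|, p = 1 − (2Φ(s) − 1)^{L′} using independence
  of the (distinct-cohort) studies; robust to effect heterogeneity.
* **wFisher**: each study's p-value is mapped through the upper-tail
  quantile of a gamma(k_l, scale 2) with shape k_l = L·n_l/n
  proportional to the study's effective sample size (harmonic mean of
  cases and controls for case-control studies, total n for continuous
  outcomes); the sum is gamma(Σk_l, 2) under the null. With equal
  sample sizes every k_l = 1 and the method is exactly Fisher's
  −2Σlog p. When a SNP is missing from some studies the shapes are
  recomputed over the available subset so they sum to L′ and the null
  stays exactly gamma. The upper-tail orientation (small p → large
  contribution) is forced by the Fisher reduction.

Gene-level combination across ancestries uses wFisher on the
single-ancestry ARTP gene p-values (Gene-wFisher) or their minimum
(Gene-minP, calibrated by applying the same operator to every
replicate row). Path-joint combines the L single-ancestry ARTP pathway
p-values with wFisher. The composite ACAT-IVW-wFisher merges the
SNP-IVW and Gene-wFisher pathway p-values through the equal-weight
Cauchy combination T = ½Σ tan((0.5 − p)π), p = ½ − arctan(T)/π, which
tolerates the strong dependence between the two inputs; inputs are
clamped to [1e-15, 1 − 1e-15] and resampling zeros floored first.

## Preprocessing

Mirroring standard practice for published GWAS: genome-wide significant
SNPs (p < 5×10⁻⁸) and all SNPs within 500 kb of one are excluded per
study (union of zones; idempotent); standard errors are inflated by
√λ of the study's genomic-control factor, with p recomputed from the
deflated z; SNPs below 1% MAF in an ancestry's reference panel are
removed from that ancestry only. SNPs are assigned to a gene when they
lie within 50 kb of the gene boundary (1-based inclusive coordinates,
window inclusive at both ends; a SNP may serve several genes), or by a
user-supplied assignment file. Alleles are harmonized against each
panel (match, flip-with-sign-change, or drop; strand-ambiguous A/T and
C/G SNPs are kept but flagged, optionally dropped).

## The simulator

`tapa.simulate` emulates the five-population study design the analysis
assumes: case-control (or continuous-outcome) studies of 4,000 (AFR),
6,000 (AMR), 6,000 (EAS), 10,000 (EUR) and 4,000 (SAS) subjects at
full scale with equal cases and controls, 500-individual reference
panels, a pathway of independent gene blocks, and per-SNP regression
summaries. The desk profile runs at 1/5 of these sizes with a 20-gene
pathway of 6 SNPs per gene.

Genotypes come from a latent-Gaussian threshold model: per gene and
population, two latent haplotypes with AR(1) correlation (ρ drawn
uniformly in [0.2, 0.8] per block and population) are thresholded at
the population allele frequency and summed. Population frequencies
follow a Balding–Nichols model around a shared ancestral frequency
(U(0.05, 0.5)) with divergence parameters 0.08–0.15, so a SNP can be
common in one population and rare (hence filtered, hence missing) in
another. The per-population MAF filter scales with the profile
(`maf_min = 0.01/scale`, capped at 0.05): the full design's 1% filter
keeps minor-allele counts above ~80, and preserving that count regime
at reduced sample sizes keeps the per-SNP statistics inside the
asymptotic range the analytic null distributions assume — at scale 1
it is exactly the 1% filter. The generator preserves exactly the
features the methods consume —
population-specific LD and MAF spectra, shared and private SNPs,
independence across genes — and makes no attempt to match any real
haplotype map; absolute power numbers are therefore not comparable to
analyses built on real LD, only orderings and error rates are.

Disease risk follows logit P(Y=1|G) = α + β Σ_{f∈R} g_f with one
functional SNP per causal gene; α is solved by root-finding so the
population prevalence hits its target (default 0.01) against the
exactly-enumerated distribution of the linear predictor. Cases and
controls are sampled retrospectively; under the global null the
outcome is independent of all genotypes, so labels are assigned
directly (distributionally identical and ~100× cheaper), and under a
risk model only the causal blocks go through rejection sampling while
the remaining genes are drawn directly for the retained individuals —
again exact, by block independence.

Per-SNP binary summaries use the logistic score test (z = U/√I) by
default; the full Newton–Raphson Wald fit is available as an option.
The two agree asymptotically, but at reduced sample sizes the Wald z
is measurably light-tailed, which biases extreme-value-based methods
(SNP-max, Gene-minP) conservative against the exactly-normal null
replicates; the score statistic's null is standard normal to high
accuracy at every MAF and sample size in the profiles. Continuous
outcomes use simple linear regression with exact t(n−2) p-values and a
standard error calibrated so the z-score is the matching normal
quantile — again so that observed z-scores are exchangeable with the
normal null replicates at any profile scale, as they are automatically
at real GWAS sample sizes.

One mild finite-scale effect remains by design: the LD matrices feeding
the null replicates come from 500-individual panels (the stated study
condition), while the observed z-scores carry the study-sample LD.
That mismatch leaves the per-ancestry ARTP p-values — and most visibly
their combinations Path-joint and Gene-minP — slightly conservative at
reduced study sizes (rejection ~0.03 at nominal 0.05 in the binary
desk profile, as the packaged calibration study reports); the deficit
is attributable to that estimation noise and shrinks as panel and
study sizes grow toward the full design. Type I error is never
inflated.

Four risk-model settings drive the power studies: **common** (same
causal genes, same central functional SNPs, one effect size β
everywhere); **distinct1** (same genes/SNPs, effects scaled by −1.4,
−1, −1, 1, 1.4 across populations); **distinct2** (same genes,
population-specific functional SNPs); **distinct3** (shifted,
partially overlapping causal gene sets — the gene-consistency
assumption only partially holds). The desk profile uses 4 causal genes
(shift step 1 in distinct3, keeping most causal genes shared by three
or more populations, as in the full design) and effect sizes inflated
to keep power in the informative (0.2, 0.9) range at 1/5 sample sizes:
β = 0.12 (common), 0.16 (distinct2), 0.18 (distinct3), with functional
SNPs observed. A 1:10 case-control variant matches the equal-ratio
design's effective sample sizes (4× harmonic mean) population by
population.

## Numerical choices

* Empirical p-value counting uses a single stable argsort plus a
  running maximum per column (ties resolved exactly, no floating-point
  equality on transformed values); it is verified bit-exact against a
  literal O(M²) double loop.
* The vectorized wFisher path evaluates the gamma upper-tail quantile
  through a cached monotone PCHIP interpolant per distinct shape
  (relative error < 1e-7 for p down to 1e-300, ~30× faster than the
  exact routine, which the scalar API retains); shape 1 is exactly
  −2 log p.
* ACAT uses 1/tan(πp) for p ≤ ½ and arctan(1/T)/π for T > 1 to keep
  precision at extreme p-values.
* Seeds: one master seed; every draw stream is derived from it and a
  stable key (dataset index, ancestry label, cluster id) via
  `SeedSequence`, so results are independent of gene/pathway/dict
  evaluation order and bit-reproducible.
* Tie order for reported gene subsets: ascending gene p-value, then
  lexicographic gene id.

## Problem sizes used by the checks

The packaged studies run at the desk profile: Type I error over 1,000
null datasets per outcome type (M = 1,000), uniformity checked on the
same p-values, and power orderings over 150 datasets per setting.
These sizes give ±0.014 (99% binomial) resolution on a 0.05 rejection
rate and ~0.04 Monte-Carlo SE on power estimates, enough to resolve
the orderings asserted; `scripts/acceptance.py` reruns the Type I
error study from scratch and reports rejection fractions at α = 0.05.

## Known limitations

* No liftover, imputation, INDEL handling, or non-integer dosages;
  biallelic SNVs only.
* LD matrices are gene- or cluster-scoped, never genome-wide; no
  banded approximation is provided.
* Path-joint's final combination is analytic (gamma tail of combined
  grid-valued p-values), so its null is exact only up to the 1/(M+1)
  grid resolution.
* The competitive null hypothesis (pathway genes vs genome background)
  is out of scope; all tests are self-contained.
* The simulator's threshold-model LD attenuates the latent AR(1)
  correlation (quantified by the bivariate-normal orthant oracle in
  the tests) and contains no recombination-map realism; passing power
  orderings here demonstrates the methods' relative behavior under the
  stated risk models, not absolute power on real genomes.
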