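# Methods

`mitoepi` implements a pipeline for studying how mitochondrial DNA variants,
alone and in interaction with nuclear variants, associate with a quantitative
trait (BMI, kg/m²). This note records the statistical models, the defaults
and why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical and design choices that were genuinely open.

## Data model

Genotypes live in a samples × variants dosage matrix counting alternative
alleles: diploid nuclear sites take values 0/1/2, mitochondrial sites are
coded haploid 0/1 on the homoplasmy assumption (all mtDNA copies share the
allele). Heterozygous-looking diploid calls on a mitochondrial contig are
potential heteroplasmy; they are set to missing and counted, never silently
coerced, because coercion in either direction would bias the allele
frequency. Missingness is NaN — a dedicated non-dosage flag — and every
statistic (MAF, call rate, HWE, kinship, association) masks it explicitly.
Coordinates are 1-based (VCF convention). Gene intervals come from BED and
are half-open; a variant at position `pos` belongs to `[start, end)` iff
`start <= pos < end`, with the boundary `pos == end` excluded (this exact
convention is asserted in tests, since off-by-one here silently changes
gene-set restrictions).

The mitochondrial 0/1 coding halves the dosage range relative to a 0/2
convention and therefore doubles β for the same biology; output metadata and
this note record the coding because interaction effects are
coding-dependent (see below).

## Quality control

The cascade runs in a fixed order — sample/variant call rate → duplicate
resolution → heterozygosity outliers → Hardy–Weinberg → kinship pruning →
PCA outliers → MAF filter — and is deterministic: identical input yields an
identical, JSON-serializable report with per-stage removals and reasons.

Defaults: sample call rate 0.95 (0.99 on the mitochondrial subset, which is
small enough that a few missed calls matter), variant call rate 0.95, HWE
P < 1e-5 (diploid variants only; haploid sites have no heterozygote class),
kinship 0.0442 (the third-degree-relative boundary), MAF 0.05 with an
inclusive boundary (maf == threshold is kept), and 3-SD windows for the
heterozygosity and PC-score outlier flags. The outlier windows are
conventional choices, not estimated quantities. The PCA flag is a
lightweight stand-in for reference-panel ancestry assignment: it catches
samples that separate on the leading PCs of the MAF-standardized genotype
matrix, which is where ancestry outliers appear, but it cannot label
populations.

The HWE test is the plain exact conditional test: given the allele counts,
it sums the probabilities of all heterozygote counts whose probability does
not exceed the observed one. Mid-p is deliberately not used, so the stated
threshold acts conservatively. Totals above 5000 fall back to a 1-df
chi-square (flagged in the result); below that the enumeration is exact and
is verified against an integer-arithmetic oracle for every table with
total ≤ 50.

## Kinship and the GRM

Pairwise relatedness uses the KING-robust between-family estimator over
jointly non-missing diploid SNPs,

    φ̂ = (N_het,het − 2·N_opposite_hom) / (N_het(i) + N_het(j)),

which is invariant to allele-label flips and gives exactly 0.5 for a sample
against itself. Pruning is greedy: repeatedly drop the sample in the most
over-threshold pairs (ties: lower call rate, then the lexicographically
larger id) until no pair exceeds the threshold — the result is checked
post hoc.

A practical caveat the package makes explicit: φ̂ has a sampling SD of
roughly 0.05 with a 300-SNP panel and 0.013 with 5000 SNPs (measured on
simulated unrelated cohorts). The third-degree cutoff 0.0442 is therefore
only meaningful when the panel is a few thousand SNPs or larger; on the
300-SNP demo cohort the bundled configuration prunes at the duplicate-level
cutoff 0.354 and leaves sib-pair correlation to the GRM random effect,
which is precisely the mixed model's job. Tests exercise the 0.0442 default
at 5000–8000 SNPs, where it cleanly separates the 20 embedded sib pairs
from the unrelated background.

The GRM is the realized relationship matrix Z Zᵀ/m over polymorphic diploid
SNPs, with Z the (2p-centered, √(2p(1−p))-scaled) dosage matrix and missing
entries mean-imputed. It replaces ancestry-adjusted estimators
(PC-AiR/PC-Relate-style): the statistical contract — a kinship-aware
random effect — is preserved, and the GRM source is pluggable (a
pre-computed TSV can be supplied) for cohorts with strong structure.

## Mixed-model association (mitoGWAS)

The trait model is y = Xb + gβ + u + ε with u ~ N(0, σ²_poly K) and
ε ~ N(0, σ²_e I). The covariate-only null is fitted by REML with the scale
profiled out, so only the variance ratio γ = σ²_poly/σ²_e is searched
(bounded Brent on log γ, tolerance 1e-8, after one eigendecomposition of
K); γ at the lower search bound is snapped to zero. Each variant is then
tested by GLS with γ held at its null estimate — the eigendecomposition
whitens the covariance — while the overall residual scale is re-estimated
within the per-variant model. Holding the ratio but refreshing the scale was
chosen so that with K = I (or no GRM at all) every statistic — β, SE and the
two-sided Wald p (normal reference) — reduces *exactly* to ordinary least
squares with covariates, which makes the estimator fully auditable against
a brute-force oracle; the alternative (freezing both components) differs
from OLS in the SE by a factor that vanishes only asymptotically.

Missing dosages are handled per-variant complete-case (the per-variant n is
reported); under a GRM the covariance is re-factorized on the subset.
Monomorphic variants yield an NA-effect row with a reason code rather than
an exception, so a scan never dies mid-table. Scan p-values are reported
unadjusted, with a Benjamini–Hochberg FDR column attached as a clearly
marked extension.

## Dispersion screen (vQTL prefilter)

To limit the number of interaction hypotheses, nuclear SNPs are
pre-screened by a variance-QTL signature: if an unmodelled interaction
involves a nuclear SNP, the residual spread of a model without that
interaction differs across the SNP's genotype classes. Two nested models
are fitted — (1) trait ~ covariates + mito variant, (2) the same plus the
nuclear variant — and each residual vector is summarized by a conditional
dispersion statistic over the nuclear genotype classes.

The selection test permutes genotype-class labels (equivalently, residual
order) while holding both residual vectors fixed, and refers the
dispersion statistic of the *richer* model's residuals (rd2) to its
permutation distribution; keep = perm_p ≤ α. The two models' residuals
differ only by the nuclear main-effect projection, so rd2/rd1 ≈ 1
identically and a ratio-based permutation test had zero power in
simulation; rd1, rd2 and their ratio are nonetheless reported, and
`require_rd_increase=True` adds rd2 > rd1 as a conjunct for users who want
the directional model-1-vs-model-2 comparison enforced.

The statistic itself was a genuinely open design choice, settled by a
power study run under two alternatives — a single clean interaction
(β_inter = 1.5, n = 1000, mito/nuclear MAF 0.1/0.3) and a diluted regime
with 25 simultaneous interactions whose combined variance contribution
shrinks every individual signature — with permutation calibration checked
under the null in both:

* **`"levene"` (default)** — the classic one-way Levene F on squared
  residuals across classes. Weakly dominant: clean power 0.42 (tied with
  rd-sd), best diluted power, null keep rate ≈ α.
* **`"rd-sd"`** — weighted relative-scale heterogeneity
  RD = Σ_g (n_g/n)(s_g/s − 1)² with per-class standard deviations; tied on
  the clean alternative, slightly weaker under dilution.
* **`"rd-mad"`** — the same with SD-consistent MADs. Deliberately not the
  default: an interaction inflates a class's dispersion through the
  minority of mitochondrial-allele carriers inside it (10–20% of the
  class, shifted by β·g), a contamination pattern a median-based scale is
  by construction insensitive to (~3× lower power, 0.12 vs 0.42); it
  remains available for heavy-tailed traits.

Also evaluated and rejected: Brown–Forsythe on absolute deviations from
class medians (lower power on both alternatives), dosage-trend statistics
on r² and |r| (no consistent gain), tail-weighted scales (75th-percentile
shortfall, 90th quantile — their own estimation noise outweighed the tail
signal), and a coefficient of variation on residuals (residual means sit
at zero, making it unstable).

Permutations default to B = 200, giving a p-value resolution of 1/201 and a
keep rule perm_p ≤ α with α = 0.05 by default; classes need at least
min_class_size = 10 members (a class of 1–9 members blocks selection with a
"sparse class" flag); rd1 is floored at 1e-12 when used as a denominator.
Each variant's permutation stream is seeded from a mandatory master seed
plus a CRC of the variant id, so a genome scan is reproducible and
insensitive to variant order.

Measured operating characteristics (defaults; n = 1000, mito MAF 0.1,
nuclear MAF 0.3): null keep rate ≈ α; power ≈ 0.42 at β_inter = 1.5 and
≈ 0.64 at 2.0, dropping to ≈ 0.14 per SNP when 25 such interactions act
simultaneously (their combined variance dilutes each signature);
β_inter = 0.5 is below the detection floor at this sample size, so the
power curve is flat between 0 and 0.5 and rises steeply after 1.0. The
screen also fires on pure variance effects (a vQTL with no interaction at
all) — intended behaviour for a prefilter, not a false positive, but worth
remembering when interpreting the kept set.

## Interaction model and decomposition

For a candidate pair, two nested models are fitted:

    S:  y ~ covariates + g_m + g_n
    I:  y ~ covariates + g_m + g_n + g_m·g_n

reported as: the nuclear effect and p in S (`nuc_eff_single`), the nuclear
and mitochondrial main effects in I (`nuc_eff_joint`, `mito_eff_joint`),
the interaction coefficient with its SE and Wald p (`inter_eff`,
`inter_se`, `inter_pval`), and a 2-df joint test of (nuclear, interaction)
(`joint_pval`). The joint test is the Wald quadratic form referred to the
exact F(2, n−k) distribution, which for least squares coincides *exactly*
with the nested-model sum-of-squares F comparison of model I against
`covariates + g_m` — the interpretation adopted for a "joint" p reported
alongside interaction terms. The product term uses raw dosages (haploid 0/1
× diploid 0/1/2) with no centering, so `inter_eff` is in trait units per
(mito allele × nuclear alt-allele count) and rescaling a dosage by c
rescales it by 1/c exactly; `center=True` is available. Pairs with a
constant product term (e.g. no carriers of both minor alleles) come back
flagged "untestable" rather than raising.

The interaction stage defaults to plain least squares (no GRM): after
kinship pruning the residual relatedness is modest, and the OLS path is
exactly oracle-checkable; a GRM can be passed to run the same fits under
the null-ratio GLS whitening. An expression-level analogue
(`expression_interaction_glm`) fits trait ~ age + sex + nuclear mRNA +
mitochondrial mRNA + product on continuous abundances — effects are per
expression unit and therefore tiny for count-scale inputs (≈1e-5 for a
product of two count-scale transcripts); only signs and significance are
comparable across scales. Gene-set over-representation of interaction hits
is a one-sided Fisher exact test of hit genes against a listed set within a
stated universe.

## Synthetic cohorts

The generator draws diploid nuclear SNPs in HWE (Binomial(2, maf) via two
thresholded latent-Gaussian haplotypes), optional AR(1) latent correlation
within blocks for tunable LD without haplotype panels, full-sib pairs
(per-SNP Mendelian transmission from simulated parents, which concentrates
realized kinship at 0.25), and haploid mitochondrial variants shared
maternally within a sib pair. The trait is

    bmi = β₀ + Σ β_c·covariate + β_mito·g_m + β_nuc·g_n + β_inter·g_m·g_n
          + u + ε,  u ~ N(0, σ²_poly K_true),  ε_i ~ N(0, σ²_e·m(g_n,i)²)

with K_true the pedigree (sib-block) relatedness and m(·) optional
per-genotype residual-SD multipliers for injecting pure variance effects.
The polygenic term is drawn from the pedigree kinship rather than a
realized genome-wide GRM: exact, cheap, and sufficient to exercise the
mixed model. Defaults describe a small clinical cohort: n = 1000, 500
nuclear SNPs, 30 mitochondrial variants, age ~ N(28.5, 5) years,
sex ~ Bernoulli(0.5), glucose ~ N(100, 15) mg/dL, baseline BMI 24 kg/m²,
σ_e = 1. Everything is bit-reproducible from one seed.

What the generator does **not** emulate: coalescent-realistic LD and allele
frequency spectra, genotyping/imputation error, heteroplasmy fractions,
population stratification beyond what the PCA flag needs, X-chromosome
and sex-specific effects, and longitudinal phenotypes. Tests passing on
these cohorts therefore demonstrate the *statistical contracts* (exactness,
calibration, power at stated effect sizes, determinism) — not performance
on any specific human cohort, whose published coefficients come from
controlled-access data and are not reproducible here.

## Problem sizes used in validation

The shipped test-and-acceptance runs use: oracle equivalence at n = 200
(10 variants, agreement to 1e-8); null calibration over 2000 simulations at
n = 500 (both tests within [0.040, 0.060] at the 5% level); effect recovery
over 200 replicates at n = 1000 for β_mito = −0.7 and β_inter ∈ {−2.225,
4.015} (bias under half an empirical SE, sign agreement > 95% among
significant fits); kinship at 5000 SNPs (50 sib pairs, mean φ̂ in
[0.20, 0.30]); the screen at 500 variants × n = 1000 (null keep rate inside
the binomial band, truth enrichment in ≥ 90% of 50 replicates with 25 true
interactors at β = 1.5, keep rate non-decreasing over β ∈ {0, 0.5, 1, 2}
with paired seeds up to one paired Monte-Carlo SE for adjacent ties); and
the demo pipeline run twice for byte-identical outputs. These sizes keep a
full run in the minutes range on a single core while leaving each check
statistically meaningful.

## Known limitations

* The dispersion screen's power is effectively zero below β_inter ≈ 1 at
  n = 1000 with the default α; it is a hypothesis-reduction device, not a
  discovery test, and its kept set should always feed the explicit
  interaction model.
* KING-based pruning needs thousands of SNPs before the third-degree
  cutoff is meaningful (noise floors above).
* The REML machinery fits a single variance ratio; multiple random effects
  (e.g. separate household and genetic components) are out of scope.
* BCF/bgzip, phased haplotypes, non-integer imputation dosages and
  multi-allelic records are not supported; multi-allelic sites must be
  pre-split.
* How heteroplasmic array calls should be resolved is left open (they are
  flagged missing); a heteroplasmy-aware coding would need intensity-level
  data that the pipeline does not model.
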