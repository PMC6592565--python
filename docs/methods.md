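# Methods

`prsphewas` implements a polygenic-risk-score (PRS) construction and
phenome-wide association (PheWAS) pipeline for related disease subtypes, with
a synthetic-data generator that reproduces the statistical structure the
analysis assumes. This note documents the models, the defaults and why they
were chosen, the numerical choices, and the limits of what the synthetic
tests demonstrate.

## Synthetic data model

**Genotypes.** Dosages are hard genotype calls (0/1/2 of a designated counted
allele, A1) generated from a latent Gaussian copula: within each LD block the
latent variables are equicorrelated and each of the two haplotype draws is
thresholded at Φ⁻¹(MAF) under Hardy–Weinberg frequencies. Thresholding
attenuates the latent correlation, so the latent equicorrelation is calibrated
numerically (bivariate-normal CDF via Owen's T, solved with Brent's method)
until the realized *dosage* correlation matches `within_block_r`. One MAF is
drawn per block (from `maf_range`, default 0.05–0.5); correlated variants
sharing a frequency is both what makes exact calibration possible and a
reasonable caricature of real LD blocks. Blocks span < 1 Mb (5 kb spacing)
and distinct blocks are separated by > 1 Mb, so the 1 Mb clumping and
locus-merging windows distinguish within-block from between-block pairs.
Variants receive forward-strand allele pairs; a configurable fraction
(`qc_injection_rates["ambiguous"]`, default 5%) are strand-ambiguous (A/T or
C/G) so the harmonization QC has targets.

**Disease architecture.** Three subtypes (default prevalences 0.05/0.08/0.05,
an enriched-cohort regime) draw causal loci from *distinct* LD blocks: six
shared loci with effects identical across subtypes, plus ten unique loci per
subtype, log-odds-ratios ~ Normal(0, `effect_sd`²) with `effect_sd = 0.3`.
Disease status follows logit P = α + Σᵢ βᵢGᵢ with α solved numerically
(Brent) so the realized prevalence matches the target in expectation.

**Phenome.** Secondary traits (default two, prevalence 0.10) are driven by
the standardized shared-locus score with a log-OR of 0.5 per SD — strong
enough that a shared-genetics signal is detectable at phenome-wide
significance in a few thousand subjects, which is the regime the pipeline is
meant to exercise. One hundred independent null codes (prevalences 0.03–0.15)
provide the false-positive floor. Every trait emits dated ICD events under
one ICD9 and one ICD10 alias (vocabulary chosen at random per event, ~30% of
carriers get a later repeat event so first-date logic is exercised); dates
are uniform over a 10-year window, which yields all orderings needed by the
365-day secondary-predictor rule. The parent "skin cancer" phecode is not
emitted directly; it is acquired through hierarchy propagation when events
map to a subtype code, which produces the same incidence table. Subjects
carry sex, integer age, a two-level genotyping-array label and four
standard-normal PCs (an optional `pc_confounding` knob loads PC1 onto the
liability; off by default).

**Discovery GWAS.** An independent cohort (default n = 20,000) with the same
variant panel is simulated and per-variant marginal logistic regressions
(vectorized Newton iterations) produce log-OR, SE, Wald p, EAF and N. QC
defects are then injected: non-ambiguous rows are strand-flipped (both
alleles complemented) or given an EAF shifted by ±0.30, each at rate 5%;
rows at ambiguous panel variants get an effect allele matching neither panel
allele. The injection log is available separately so round-trip tests can
verify 100% repair/exclusion without the stats table leaking truth.

## Harmonization and QC

Catalog-style entries are matched to panel alleles: direct match kept;
complement match at a non-ambiguous variant corrected (minus-strand
assumption); ambiguous variants without a direct match excluded; missing
risk allele/RAF/OR and non-European ancestry labels excluded. The RAF filter
drops entries whose reported risk-allele frequency deviates from the control
cohort frequency by more than 0.15 in absolute allele-frequency units
(chromosome-X frequencies use female controls only). Correlated entries
(r² > 0.1 on control dosages) and duplicate IDs keep the most recent
publication date, ties broken by smaller p. RAF filtering runs before LD
dedup. Every input row receives exactly one machine-readable fate in the
audit table. Inputs must share one coordinate system; no liftover is
attempted (validated, not converted). Note that for single-base risk alleles
at non-ambiguous SNPs, a "no allele match" can only arise from data errors:
every base or its complement matches one of two non-complementary alleles.

## Clumping, thresholding, reweighting

LD is the Pearson correlation of dosage vectors, zeroed beyond 1 Mb or
across chromosomes; monomorphic variants get r = 0 with a warning. Clumping
is single-pass greedy by ascending p (ties by chromosome, position; entry
threshold p < 5×10⁻⁴, r² > 0.1, MAF > 0.5%), then nested subsets at
p < 5×10⁻⁹ … 5×10⁻⁴ with summary-statistic log-ORs as weights. All
inequalities are strict.

The point-normal reweighting works on the standardized-genotype scale
(β_std = z/√N) and back-transforms per-allele weights by 1/√(2f(1−f)); the
absolute phenotype-scale constant cancels in scoring and standardization.
The infinitesimal solution solves (M/(Nh²)·I + D)w = β̂ per chromosome with
D banded at the SNP radius (default 2,800, a sliding band rather than
disjoint chunks); singular systems get a 10⁻⁶ ridge jitter. The Gibbs
sampler residualizes each variant against its neighbors' current sampled
effects, computes the posterior inclusion probability under the point-normal
prior (causal fractions 100%…0.001%, per-causal variance h²/(Mf)), samples
inclusion and effect, and accumulates Rao-Blackwellized posterior means over
1,000 post-burn-in sweeps (burn-in 100). Those chain lengths are desk-scale
defaults — at M ≈ 500 the fraction-1 chain reproduces the closed form within
Monte-Carlo error — and both are exposed in `LdpredConfig`. Per-variant MC
standard errors come from batch means (10 batches); a chain whose sampled
heritability exceeds 1.5× the prior h² (plus a 0.05 floor for tiny-h² cases)
aborts with a diagnostic. The "auto" h² uses the aggregate estimator
M(mean χ² − 1)/(N·mean LD score), clamped to [0.01, 0.99] with a warning.

## Scoring and decomposition

PRS_j = Σ βᵢGᵢⱼ with allele-flip handling (d → 2−d when the matrix counts
the other allele) and a hard error when an effect allele matches neither
matrix allele. Missing model variants are skipped by default and reported as
un-scored weight mass (`coverage`); a strict mode raises. Standardization is
(x − mean)/SD with the n−1 sample SD, recomputed per analytical set.

Loci merge by single-linkage chaining at 1 Mb on one chromosome. The shared
PRS takes one representative SNP per locus present in all three subtype
models — the member with the smallest source p-value, ties by coordinate —
with every weight set to 1; since the unweighted score counts *risk-increasing*
alleles, a representative whose source weight is negative has its effect
allele flipped to the other allele. Unique PRS keep original weights for
loci private to one model. Whether to use one representative or all member
SNPs per shared locus was an open choice; one representative keeps the
"unweighted sum of risk alleles of loci" interpretation exact.

## Phenome construction and matching

ICD events map to phecodes by table lookup; a subject carries a phecode when
any event maps to it or a descendant (ancestors are added by the digit-based
hierarchy: 172.11 → 172.1 → 172), first date = earliest mapping event.
Controls for a phecode exclude carriers of the phecode and of any
hierarchical relative (configurable off). Studies require case counts
strictly above 50.

Matching is nearest-neighbor Mahalanobis on standardized age + PC1–4 with
exact matching on sex and array, up to 10 controls per case, without
replacement, cases processed in ascending subject-ID order. The caliper is
interpreted **per covariate**: every standardized matching covariate must
agree within 0.25 SD. This is the interpretable, exactly testable reading,
but it is deliberately strict: with five mutually independent covariates the
probability that a random control is simultaneously within 0.25 SD on all
five is ≈ 0.14⁵ ≈ 5×10⁻⁵, so high matched ratios are achievable only when
control covariates overlap cases tightly (scalar-distance calipers, as in
propensity-score matching, behave very differently). Consequently the
matched mode drops studies whose matchable case count falls to ≤ 50, and
the phenome-scale statistical checks run in the unmatched sensitivity mode,
which the analysis supports as a first-class configuration. The matching
contract itself (exact equality, caliper compliance, ratio ≥ 9 at pool/case
≥ 30) is verified on pools constructed with overlapping covariates.

## Association and evaluation

The Firth fit maximizes l(β) + ½ log det I(β) by modified-score Newton
iterations with step-halving, converging when the modified score falls below
10⁻⁸; estimates are finite under complete separation, and on saturated 2×2
tables the slope equals the half-cell-correction closed form to < 10⁻⁶.
Frequency weights are supported (a saturated table is a 2-row weighted fit).
Rank-deficient designs raise, naming the aliased columns. Wald p-values are
the default; penalized-likelihood-ratio p-values (each coefficient profiled
to zero *inside the full model*, so the Jeffreys penalty keeps its dimension)
are available by flag — profiling in a reduced model would change the
penalty and badly inflate the statistic.

PheWAS fits PRS + age + sex + array + PC1–4 per study, PRS standardized
within the study's analytical set, zero-variance covariates dropped with a
log entry (this also handles single-sex phenotypes), Bonferroni threshold
α / (studies actually tested). Exclusion PheWAS removes carriers of the
exclusion phecodes from every study, drops the excluded studies themselves
and re-derives the Bonferroni denominator. The secondary-predictor model
codes prior secondary diagnosis as 1 when the first primary diagnosis came
≥ 365 days later or never, excludes subjects whose primary fell inside the
lag (or preceded the secondary), and fits the same covariate set.

A behavior of the secondary-predictor model worth knowing: under the
synthetic phenome's uniform, mutually independent diagnosis dates, the lag
rule excludes exactly the subjects whose primary diagnosis followed the
secondary within a year (or preceded it), which removes a large share of the
double-diagnosed subjects from the predictor-positive group. That selection
pushes the coefficient downward and, at the default effect sizes, outweighs
the genetic enrichment — so a negative synthetic coefficient reflects the
date model, not a failure of the lag-rule implementation (real precursor
conditions are diagnosed years before the primary disease, a structure the
uniform date model deliberately does not encode).

Evaluation fits a PRS-only logistic model (statsmodels MLE with a Firth
fallback on separation — the unpenalized/penalized choice was open and is
resolved this way) on a stratified 1/3 training split and computes, on the
2/3 test split: Mann–Whitney AUC with a DeLong-variance 95% CI, the
Hosmer–Lemeshow χ² over deciles of predicted risk (empty deciles merged, df
adjusted; heavy ties fall back to grouping by distinct predictions), the
Brier score, and Nagelkerke's pseudo-R² from test-set log-likelihoods.

## Catalog

Weight files round-trip losslessly at ≥ 9 significant digits. The PheWAS
JSON payload (one record per phecode with −log10 p, direction, OR and CI,
plus the Bonferroni threshold and PRS provenance) validates against a
shipped JSON schema; records with undefined p are flagged, not dropped.
The static HTML tree (index plus one page per trait × method, with embedded
JSON, download links and an SVG Manhattan plot colored by the integer part
of the phecode) is rendered with plain string templates and requires no
server.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks run at sizes chosen to make their statistical
assertions sharp while keeping a desk-scale footprint: CI-coverage
replicates use n = 8,000–10,000 subjects with 20 independent causal
variants; phenome specificity uses 50 replicates of 3,000 subjects, 400
variants and ~105 studies; the Gibbs-vs-closed-form comparison uses M = 500,
N = 10,000, 5 chains of 1,000 sweeps; type-I error uses 5,000 null Firth
fits. The acceptance script reruns the whole pipeline at n = 4,000 subjects
with a 20,000-sample discovery cohort.

## Known limitations

* LD is block-equicorrelated with per-block MAFs — no realistic human LD
  maps, no cross-block LD, no relatedness, no imputation uncertainty, and no
  non-European frequency structure.
* Dosages are hard calls; real imputed dosages are continuous in [0, 2]
  (the scoring and LD code accept continuous values; only the generator is
  discrete).
* Marginal discovery effects attenuate relative to joint generative effects
  when many causal variants act at once (non-collapsibility); single-causal
  configurations are used where the oracle requires the marginal to equal
  the generative value.
* The per-covariate caliper makes organically matched phenomes sparse, as
  discussed above; passing matched-mode tests therefore demonstrates the
  matching contract, not epidemiological realism of 10:1 matched designs.
* Nearest-gene locus naming is accepted as input, never computed.
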