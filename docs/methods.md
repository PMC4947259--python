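# Methods

## The study design being emulated

The pipeline targets an association panel built from six full-sib families
of a self-incompatible, outbreeding grass. Each family derives from a
single pair cross followed by seed multiplication in isolation, and 60
offspring per family are genotyped by genotyping-by-sequencing (GBS) —
sparse, missing-data-rich SNP calls. Days to heading (from April 1st) is
recorded in two years × two field replicates; aftermath heading — seed-head
reappearance in regrowth after cutting, an undesirable forage trait — is
scored once on an ordinal 1–9 scale. Because the parents themselves were
never genotyped, all marker selection is inferred from offspring
segregation. No real accessions ship with the package; the synthetic-data
module generates cohorts with this structure.

## Synthetic-data generator (`simdata`)

**Meiosis.** Crossovers are a Poisson process on the cM scale with no
interference (Haldane), so the recombination fraction over d cM is
r = (1 − e^(−2d/100))/2. This is the simplest model consistent with a cM
map. Gametes are sampled per linkage group from phased parental
diplotypes; `F2_sibmated` mode (the default cross) first produces an F1
cohort (default 30 plants) and draws offspring from random matings of
distinct F1s, mimicking one pair cross plus seed multiplication;
`F1_fullsib` mode mates the two parents directly and is used for
controlled unit experiments. Which generation the real 60 offspring
represent is not knowable from the design description, so both modes are
first-class.

**Parents.** Per locus, parents are hom × het (the pseudo-testcross
configuration) with probability 0.5, het × het with probability 0.3, and
both homozygous otherwise. These are plausible GBS heterozygosity levels
for an outbreeder and put all three segregation types in front of the
filter.

**Phenotypes.** Heading is additive:
family mean + Σ(dosage × effect) + year effect + N(0, σ²).
The aftermath score is a latent Gaussian — its own QTL plus a *negative*
coupling to the heading genetic value (earlier-heading genotypes show more
aftermath heading) — rounded and clipped to 1..9 (equivalently, unit-width
thresholds). A truth record (per-genotype genetic values, realized σ²g)
accompanies every cohort for parameter-recovery tests.

**Default study conditions** (chosen once, as the conditions the analysis
assumes): 6 families × 60 offspring; 7 linkage groups × 100 cM; 5,000
markers; call missingness 0.20 and genotype-error rate 0.01 (typical GBS);
family means 42–58 d spanning early→late crosses; +3 d year effect;
heading QTL on LG4, LG7, LG2 and LG6 (3.0, 2.5, 2.0, 1.5 d per allele) and
an aftermath QTL on LG6; residual SD 3.6 d, set so that line-mean H² over
2 years × 2 replicates is ≈ 0.88 once between-family genetic variance is
counted; 70 % of scaffolds unanchored in the zipper (roughly the observed
fraction of markers a zipper can place); physical coordinates from a fixed
1 Mb/cM scaling with each LG cut into 40 scaffolds.

**What the generator does not emulate:** read-level sequencing, alignment
or variant-calling artifacts (allele-specific dropout, paralog collapse),
segregation distortion of biological origin, spatial field trends, or
genotype×year interaction. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated model, not robustness to
those real-data pathologies.

## Filtering and pseudo-testcross selection (`filtering`)

Stages, in order, with inclusive boundaries everywhere ("at least"):
per-call GQ ≥ 30 (failing calls become missing), per-site mean mapping
quality MQ ≥ 30, presence ≥ 70 %, MAF ≥ 5 % panel-wide or ≥ 10 % within a
family. A site is a pseudo-testcross marker when one homozygous class plus
the heterozygous class account for ≥ 95 % of calls; the ≤ 5 % residual
third class is treated as genotyping error and set missing (a strict
two-class rule would discard nearly everything at realistic GBS error
rates; the tolerance is configurable). Sites with fewer than 20 calls are
unclassifiable. The 1:1 χ² statistic is the plain Pearson form
(n₁−n₂)²/(n₁+n₂), df = 1, no continuity correction, applied per site at
α = 0.05 without multiple-testing correction — segregation screening, not
inference. Stage counts are reported and are non-increasing by
construction. Notably, intermated-F2 cohorts shift many true hom×het loci
away from 1:1, so a large χ²-stage drop is expected, not a defect.

## Single-marker association (`assoc`)

Kruskal–Wallis with midranks and the standard tie correction
1 − Σ(t³−t)/(N³−N); with two genotype classes H equals the squared
standardized Wilcoxon statistic and is χ²₁ under the null. The phenotype
entering the heading scans is the mixed-model conditional mean; aftermath
heading (scored in one year) uses replicate means. Benjamini–Hochberg
q-values are computed within each family × trait scan — m is that scan's
marker count, the only scope consistent with reporting per-family tables.
An all-tied phenotype yields H = 0, p = 1 (guarded tie denominator).

## LD from unphased diplotypes (`ldtools`)

With genotype dosages the double heterozygote is phase-ambiguous, so the
haplotype frequency p_AB is estimated by maximizing the multinomial
likelihood with allele frequencies fixed at their sample values — the
classical one-dimensional "cubic equation" problem. The maximizer is found
by EM (E-step: cis fraction p_AB·p_ab/(p_AB·p_ab + p_Ab·p_aB); M-step:
reassemble p_AB from known haplotypes plus the expected cis count), run
from three starts (each admissible bound ± 1e-6 and linkage equilibrium),
tolerance 1e-10, ≤ 1000 iterations; the best log-likelihood wins and ties
resolve toward smaller |D|. Then D = p_AB − p_A p_B,
r² = D²/(p_A(1−p_A)p_B(1−p_B)), D′ = D/D_max. Individuals contribute to a
pair only when called at both loci; monomorphic loci are an error, and LD
is computed within scaffolds only (bp distance is undefined across).
Decay curves sort estimates by distance and chunk into fixed-count bins
(default 1000; the final partial bin is kept and flagged).

A practical limit worth stating: at n = 60 the double-heterozygote
ambiguity alone puts an ≈ 0.04 RMSE floor on r² versus the truth known
from phased gametes. The estimator is verified against a 1e-6 grid-search
likelihood oracle (agreement < 1e-5 in p_AB), so the gap is information,
not implementation; it shrinks well below 0.02 by n = 600.

## Mixed-model GWAS (`mlmgwas`)

Model: y = Xb + u + e, u ~ N(0, σ²g K), e ~ N(0, σ²e I), with K the
VanRaden genomic relationship matrix (column-centered dosages, denominator
2Σp(1−p)) and X an intercept plus dosage principal components (default 3 —
the appropriate count is population-specific and configurable). Restricted
likelihood is maximized over δ = σ²e/σ²g on the spectral decomposition of
S(K+I)S (the +I shift makes the null space exactly the fixed-effect space
even for singular K), with an 81-point log₁₀δ grid on [−8, 8] refined by
bounded scalar minimization. Per-marker tests hold the components at the
null optimum (P3D/EMMAX), whiten through the eigendecomposition of K, and
test each marker by residualized regression with a two-sided t test — so
with K = I and no covariates the p-values reduce exactly to ordinary
regression. Missing dosages are mean-imputed per site for kinship, PCA
*and* the per-marker tests; exact pairwise exclusion under a dense GLS
covariance would need an O(n³) solve per marker, which is disproportionate
here, and mean imputation under ~20 % missingness is mildly conservative
(it attenuates effects toward zero). With K = I, σ²g and σ²e are not
separately identifiable and only their sum is meaningful — documented
degenerate case. Thresholds: Bonferroni α/m (reported as the arithmetic
quotient; for α = 0.05 and m = 51,864 that is 9.64×10⁻⁷, whatever a
rounded report may print) and BH FDR flags; QQ data use expected quantiles
−log₁₀((i−0.5)/m).

## Phenotype statistics (`phenostats`)

Variance components reuse the spectral REML with K = ZZᵀ (Z the genotype
incidence) and year as the fixed effect; replicate is not modeled as an
effect for heading — it only contributes records — matching the stated
model, while aftermath (one year) uses replicate records directly.
n̄ is the harmonic mean of per-genotype record counts (robust to missing
records); H² = σ²g/(σ²g + σ²e/n̄). Conditional means are
intercept + σ²g Zᵀ V⁻¹(y − Xβ̂): raw genotype means as σ²e → 0, the
year-adjusted grand mean as σ²g → 0. Between-year correlation defaults to
genotype-mean values (plant-level pairing is an option) with a Fisher-z
CI. The replicate comparison is a plain one-way ANOVA F test; the
aftermath-on-heading relation is OLS with the usual t test on the slope.

## Numerical choices and degenerate inputs

- All stochastic code takes explicit seeds; the pipeline fans one global
  seed into fixed per-stage sub-seeds (SeedSequence), so stages can be
  rerun independently and deterministic stages are bit-identical.
- PCA signs follow the largest-|loading|-positive convention, making
  rotations deterministic.
- Half-open heatmap intervals [mᵢ, mᵢ₊₁), final interval closed; markers
  exactly on an interior map position go right; positions outside the map
  extent clamp to the terminal interval with a warning.
- Missing dosage is NaN everywhere and never conflated with dosage 0;
  readers count every rejected record (out-of-range scores, multiallelic
  sites, duplicate zipper anchors — first anchor wins).
- Likelihood logs are clipped at 1e-12; the EM admissible interval is
  closed before clipping.

## Problem sizes

Tests and the acceptance script run desk-scale versions of every
experiment: 5,000-marker studies for the end-to-end pipeline, 2,000
markers for GWAS calibration, 100 replicates for QTL recovery, 10,000
null markers for scan calibration, 11 REML replicates at 360 genotypes × 4
records. These sizes give stable Monte-Carlo estimates while keeping a
full run around a minute on one CPU.

## Known limitations

- The per-family scan handles only two-genotype-class (1:1) markers;
  1:2:1 het×het markers are excluded by design, as is interval mapping.
- P3D fixed variance components slightly misstate per-marker uncertainty
  when a marker explains substantial variance.
- The aftermath latent-threshold model is a convenience; real ordinal
  scoring has rater effects the generator does not simulate.
- BCF, indexed VCF access, imputation and phasing are out of scope.
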