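# Methods

This note records the statistical model behind each stage of the pipeline,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic fixtures do and do not establish about real data.

## Data model

Genotypes are additive-coded hard calls: the count {0,1,2} of the ALT allele,
with a distinct missing sentinel (−1) that is never imputed. Effect-allele
orientation (which allele is trait-increasing) is a reporting-layer relabel;
stored calls are never recoded. The phenotype is BMI = weight(kg)/height(m)²
with the binary class split at 25 kg/m² — the WHO overweight boundary for
European populations — and the boundary is inclusive (BMI = 25 → "high").
Age (years) and sex (0/1) ride along as nuisance covariates.

## Quality control

* **HWE exact test.** The conditional distribution of the heterozygote count
  given the allele counts is evaluated with the standard outward recurrence
  from the distribution mode; the two-sided p sums all outcomes whose
  probability does not exceed the observed one (plain, non-mid-p
  definition). Verified against exact-rational full enumeration to 10⁻¹² for
  every genotype triple with total ≤ 50. Variants fail QC at p ≤ 10⁻⁶.
* **Call rate** ≥ 0.99 by default (replication-style); setting it to 1.0
  reproduces discovery-style strictness (no missing genotypes at all).
* **INFO r²** ≥ 0.7 where the metadata carries an imputation quality score.
* **Stratum allele-frequency bias.** For each variant and each pair of
  sample strata a 2×2 allele-count Fisher exact test is computed (the allele
  2×2 rather than the genotype 2×3 table — a deliberate interpretation,
  since the allelic table matches the additive coding used everywhere else);
  the per-variant minimum pairwise p is Benjamini–Hochberg-adjusted across
  variants and flagged below 0.01.
* **Distance pruning** is greedy by ascending association p with an
  *inclusive* 500 kb window on the same chromosome; the globally most
  significant variant always survives. Duplicate (chrom,pos) entries keep
  the smaller p.

## Pairwise interaction statistics

* **Regression** (quantitative trait): OLS of
  `Y ~ 1 (+ covariates) + g_A + g_B + g_A·g_B`; β₃ is tested with a
  two-sided t-test. Covariates are supported but default off, so the
  uncovariated scan matches the common command-line tool behaviour.
  Missing-data policy is pairwise-complete per pair.
* **Allelic odds-ratio Z** (binary classes): each sample contributes two
  alleles per locus; the per-class 2×2 table cross-tabulates g vs 2−g at the
  two loci summed over samples, and
  `Z = (log R − log S)/√(V_R + V_S)` contrasts the case and control odds
  ratios. `V` is read as the Woolf *variance* of the log odds ratio (sum of
  reciprocal cell counts) — the convention of the tool family this statistic
  comes from, where the denominator is sometimes written loosely as a sum of
  "SE"s. Zero cells receive the Haldane–Anscombe +0.5 on all four cells of
  the affected table. Under a simulated null (n = 1000, MAF 0.3) the test's
  empirical size is ≈ 0.05, supporting the variance reading.
* **Two-locus ANOVA**: one-way ANOVA of the trait across the occupied cells
  of the 3×3 joint-genotype grid (the statistic that exhaustive
  ANOVA-pruning tools permute). A two-way main/interaction decomposition is
  deliberately not attempted; the one-way form is what gets permuted.
* The scan is brute force over all C(m,2) pairs with deterministic
  (chromosome, position) canonical ordering. Index-based pruning
  accelerations are out of scope: the intended panel is a few hundred loci,
  where the vectorized scanners complete in milliseconds.

## MDR and GMDR

A pair's 3×3 joint-genotype grid is collapsed to high/low-risk cells from
training data: high iff cases/controls ≥ the overall training ratio, with
three conventions the original method leaves open, fixed here as constants:

* exact ratio ties → high-risk;
* a cell with cases but no controls → high-risk; an empty training cell →
  unclassifiable;
* samples in unclassifiable cells are excluded from both the numerator and
  denominator of balanced accuracy, keeping 0.5 as the chance level.

The search uses stratified 10-fold cross-validation (stratified by class, or
by score sign for GMDR, to avoid one-class folds). In each fold the pair
with the best *training* balanced accuracy is chosen; the reported model is
the modal pair, CVC is the number of folds choosing it, and TBA is its mean
held-out balanced accuracy; CVC ties break by higher TBA, then canonical
order.

GMDR replaces counts with per-sample scores — residuals of the trait (or
class, via logit link) from a covariate-only GLM — and labels a cell
high-risk when its training score sum reaches the cell's size-proportional
share of the training-subset score total. Scores are centered over the full
cohort, so on the full data this is the plain "score sum ≥ 0" rule; the
recentring matters only inside CV folds, where it makes the binomial
no-covariate case reduce *exactly* to the MDR count rule (without it the two
diverge whenever a fold's class ratio differs from the global ratio). A
relative tolerance of 10⁻⁹ on the threshold keeps exact ties labelled
high-risk despite float rounding.

Permutation calibration shuffles phenotype rows (with covariates attached,
preserving their relationship under the null of no genotype effect) against
genotype rows, re-runs the whole search per shuffle, and reports empirical
(1−α) quantiles of the null best TBA plus
`perm_p = (1 + #{null ≥ observed})/(1 + B)`.

## Permutation adjustment, consensus, replication

Family-wise significance of the closed-form scans uses the max-statistic
(min-p) permutation null: `p_adj = (1 + #{null min-p ≤ observed p})/(1+B)`,
which is monotone in the observed statistic and bounded below by 1/(B+1).
The scanners factorize each pair's normal equations once, so each
permutation costs one matrix-vector product and B = 1000 is practical on a
few hundred loci.

A consensus report keeps pairs flagged (p_adj < 0.05) by ≥ 2 distinct
methods — two because each of the workflow's canonical replicated findings
carries exactly two supporting tools. Replication re-tests discovery pairs
in a second cohort with their supporting methods: closed-form methods via
the same permutation adjustment over the family of testable discovery
pairs; the MDR/GMDR path first requires the cross-validated search over the
discovery loci to select the pair with CVC ≥ 7/10, then applies the
permutation test. A pair replicates when any supporting method achieves
adjusted p < 0.05; directional consistency of effects is reported but not
enforced. Pairs with a variant missing from the second cohort are listed as
untestable rather than failed.

## Genotype-combination analysis

For a replicated pair, samples are cross-tabulated over the nine joint
genotype cells by BMI class. Each cell's prevalence (count over group
total) is compared between the high and low groups with a pooled two-sample
proportion z-test (z² equals the uncorrected 2×2 chi-square); the nine
cells are tested at raw α = 0.05 by default (a BH option exists but
defaults off, matching the workflow's reporting convention). The carrier
binomial test is one-sided against the cohort-wide low-BMI proportion as
baseline — the natural null for "carriers fall in the low-BMI group more
often than the cohort does". The variance partition reports raw and
adjusted R² of the covariates+main-effects model and the model adding the
product term; the raw ΔR² is non-negative by nesting, while the adjusted
difference can be negative when the interaction is null.

## Synthetic data: what it emulates and what it does not

Genotypes are independent draws of two Bernoulli(MAF) alleles per variant —
Hardy–Weinberg proportions with no linkage disequilibrium, mirroring a
panel pruned to ≥ 500 kb spacing. An optional two-locus haplotype-frequency
knob introduces a chosen pairwise correlation for phantom-epistasis
demonstrations. The phenotype follows the interaction regression model with
age ~ U(40, 80) years, sex ~ Bernoulli(1/2), baseline 21 kg/m², an age
slope of 0.05 kg/m² per year, a 1 kg/m² sex offset and residual SD
3 kg/m² — values chosen once so the simulated cohort is middle-aged,
BMI-realistic, and split roughly in half by the 25 kg/m² class threshold.
Heights are drawn N(170, 8) cm and weights back-derived so the
height/weight → BMI path is exercised.

Named fixtures define the study conditions used throughout the tests:

* `null` — n = 1000, 10 variants, MAF 0.3, no genetic effects;
* `planted_product` — n = 2000, 20 variants, MAF 0.3, β₃ = 1.5 (half the
  residual SD) on the product term between the first two variants;
* `planted_xor` — n = 900, 10 variants, complete penetrance: the class is
  exactly the XOR parity of the causal pair (MAF 0.5, negligible noise);
* `two_cohort` — two independent `planted_product` draws, optionally with
  the interaction removed from the second cohort.

What passing tests on these fixtures establish is internal statistical
correctness: exactness of the closed forms against independent oracles,
type-I error calibration, power on planted effects, uniformity of
permutation p-values, and the selectivity of the replication gate. What
they do not establish is robustness to features the generator omits:
linkage disequilibrium (and hence phantom epistasis), population structure,
genotyping or imputation error, missingness that is informative, or
non-Gaussian phenotype tails. Conclusions about real cohorts inherit those
caveats.

## Numerical conventions and scaled problem sizes

* p-values are clamped to (0, 1] (smallest subnormal double as floor).
* The HWE recurrence runs outward from the mode, so unnormalized masses only
  decay and cannot overflow; a 10⁻¹² relative tolerance absorbs float ties
  in the "≤ observed probability" comparison.
* ANOVA treats a phenotype whose total sum of squares is below 10⁻¹² of its
  scale as constant (F = 0, p = 1); an exactly-zero within-group sum of
  squares with between-group signal yields F = ∞ and the floor p.
* Rank-deficient pair designs (e.g. a monomorphic locus) raise immediately
  in the per-pair API and are dropped with NaN statistics in the batched
  scanners.
* Permutation replicate counts in the test suite and acceptance script are
  scaled to the fixture sizes (B between 39 and 200, replicate counts
  between 50 and 600) — large enough that the discreteness floor 1/(B+1)
  sits well below the 0.05 gates being exercised, and chosen as the
  package's own test-design sizes. B = 39 is used where a conservative
  achievable-level test is wanted (the smallest adjusted p, 1/40, is the
  only value below 0.05).
* All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; fixture files are byte-identical under identical arguments.

## Known limitations

* The allelic odds-ratio Z treats the four pseudo-allele pairings per
  sample as independent; its calibration was verified under HWE and
  independent loci, and is not guaranteed under strong LD or HWE violation.
* MDR/GMDR fold assignment depends on the seeded partition; CVC/TBA are
  reproducible given the seed but not bitwise comparable with other
  implementations' RNGs — equivalence holds at the property level.
* The exhaustive scan is quadratic in panel size and intended for pruned
  panels (hundreds of loci), not genome-wide matrices.
* Sample-level QC (relatedness, ancestry) is assumed done upstream.
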