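# Methods

## Scope and data model

The pipeline targets the classical candidate-gene design: a few biallelic
SNPs typed by PCR-RFLP or sequencing in hundreds of animals, a table of
quantitative traits with categorical management covariates, and a qPCR
panel for the gene's tissue expression. Genotypes are unordered allele
pairs (unphased); locus coordinates inside names are opaque labels, and no
genome arithmetic is performed. Missing calls are first-class: excluded
from per-locus counts, from EM tallies, and casewise from model fits, with
the exclusion counts reported at each stage.

## Per-locus statistics

Allele frequencies come from allele counting, `p = (2·hom + het) / 2n`,
never from rounded genotype frequencies — the only convention that
reproduces published 4-decimal tables exactly. Gene diversity
He = 1 − Σpᵢ², effective allele number Ne = 1/Σpᵢ² (so Ne·(1 − He) = 1
identically for any allele count), and Botstein's
PIC = 1 − Σpᵢ² − ΣΣ_{i<j} 2pᵢ²pⱼ², which for two alleles reduces to
He − 2p²q². PIC classes use the conventional cutoffs (<0.25 low,
0.25–0.50 intermediate, >0.50 high), with boundary values assigned to the
higher class.

The Hardy-Weinberg test is the plain χ² goodness-of-fit statistic over
all three genotype classes — unobserved classes stay in the sum with
O = 0 — with no continuity correction and no exact test, judged against
the fixed critical values 5.991 and 9.21 (the df = 2 convention common in
the livestock literature). Recomputing df per locus would be defensible
but would not match how such tables are conventionally read, so the fixed
values are kept and the verdict enum makes the α-level explicit. A locus
with only one observed allele yields χ² = 0 with a warning rather than an
error. Note that a χ² *below* the critical value means Hardy-Weinberg
equilibrium is *not rejected*; prose in some primary reports inverts this
wording, and the module always reports the conventional verdict.

## EM haplotype inference

Phase ambiguity: a genotype heterozygous at h of L loci is compatible with
2^(h−1) unordered haplotype pairs. The E-step distributes each genotype
class over its compatible ordered pairs (a, b) with weight ∝ f_a·f_b
(which doubles unordered weights for a ≠ b automatically); the M-step sets
frequencies to expected gamete counts over 2n. The observed-data
multinomial log-likelihood is recorded every iteration and asserted
non-decreasing in tests. Enumeration is explicit over all 2^L haplotypes
(zero-frequency haplotypes are retained in the result for bookkeeping and
removed only by the frequency filter), which bounds practical use at
roughly 12 heterozygous loci per individual — far beyond the 2-SNP designs
this pipeline targets.

Initialisation defaults to the product of marginal allele frequencies,
with a uniform option; for two-locus tables the likelihood is unimodal in
practice and both starts agree to 1e-6 (tested). Convergence is declared
when the largest frequency change or the log-likelihood change falls
below `tol` (default 1e-8, `max_iter` 1000); exhausting the iteration cap
flags the result not-converged instead of raising. An independent
coarse-to-fine search over the frequency simplex (global step 0.02,
greedy pairwise mass transfers refined to 1e-3) serves as the MLE oracle
in the tests.

Haplotypes are reported as allele strings and additionally labelled Hap1,
Hap2, … in descending frequency order; labels are presentation only.

## Linkage disequilibrium

From two-locus haplotype frequencies with designated alleles A, B (the
reference — lexicographically first — allele at each locus by default):
D = f_AB − pA·pB; D' = |D|/Dmax with Dmax = min(pA(1−pB), (1−pA)pB) for
D > 0 and min(pA·pB, (1−pA)(1−pB)) for D < 0; r² = D²/(pA qA pB qB).
D' is reported unsigned. A monomorphic margin makes both measures
undefined and they are returned as NaN rather than raising, since a
monomorphic locus is a data property, not a usage error. By default LD is
computed from the EM-fitted frequencies at full precision; a map of
user-supplied (e.g. printed, rounded) frequencies is accepted for
replication exercises.

## Diplotype assignment

Per sample, the posterior over compatible unordered haplotype pairs is
∝ f_a·f_b (×2 for heterozygous pairs), normalised to 1; the most probable
pair is reported with ties broken toward the lexicographically smallest
pair. Summing posteriors over samples reproduces the EM's final expected
gamete counts (tested), so assignment and estimation are mutually
consistent.

## The packaged study counts

The study's diplotype table lists five classes totalling 464 of 468
genotyped animals. The single-locus marginals (CT = 94 at g.19501,
CC = 192 at g.19518) force the four unlisted animals into the joint
(CT, CC) class — the carriers of the rare T-C haplotype. The packaged
joint table is therefore a *derivation* from published marginals, not a
printed table, and is documented as such in `paper_fixture`. EM on this
table returns (0.621, 0.279, 0.095, 0.005) — the published frequencies —
with D' = 0.918 and r² = 0.158.

## Association model

All terms are fixed effects fitted by OLS with reference coding. Sire is
fixed (not random) to match the source model family, although a random
sire effect would be the modern default; this is a deliberate fidelity
choice and no mixed-model switch is provided. LS means average predictions
with equal weight over the levels of every other factor (classical
population marginal means), so with balanced data and no covariates they
equal raw group means exactly (tested as an algebraic identity). The
overall factor test is the partial (Type III) F-test — with reference
coding and no interactions, the joint test that the factor's coefficients
vanish — cross-checked in the tests against `statsmodels` `anova_lm`
(typ=3, sum coding). Order-dependent sequential sums would be misleading
at class ratios like 374:94.

Pairwise level comparisons are unadjusted t-tests on LS-mean contrasts,
compared against the familywise Bonferroni threshold
α/(n_traits·n_markers) (0.05/18 = 2.78 × 10⁻³ for nine traits and two
markers); no additional Tukey-style adjustment is layered on top, since
the familywise threshold already performs that role in this design.
Rank-deficient designs (e.g. genotype aliased with sire) raise an error
naming the aliased columns rather than silently dropping them. Diplotype
association drops classes below a minimum size (default 10) with a
report, then follows the identical contract.

Compact letter displays use insert-and-absorb: start from one group of
all levels; for each significant pair split every group containing both;
absorb subset groups; order groups by their members' positions in the
descending-mean ordering and assign letters from 'a'. Letters are a
deterministic function of the p-matrix, threshold and mean ordering.

## Expression

Technical replicates are averaged on the Ct scale (standard practice;
averaging linear quantities instead would weight low-Ct outliers more).
ΔCt subtracts the arithmetic mean of the reference-gene Cts — identically
the log2 of the geometric mean of their linear quantities, i.e.
multi-reference geometric-mean normalization. ΔΔCt subtracts the
calibrator unit's mean ΔCt, so the calibrator's point estimate is exactly
1; amplification efficiency is fixed at 2.0 with no efficiency
correction. The calibrator is a required argument — typically the
lowest-expressing tissue. RQ is invariant to any additive Ct shift
applied to all genes of a run (tested), which is the property that makes
the normalization work.

Across-tissue comparison operates on log2(RQ) of biological subjects:
one-way ANOVA, then pairwise t-tests only if the ANOVA rejects (Fisher's
protected LSD), then letters. The protection step is what keeps the
all-null configuration on a single shared letter at the nominal 95% rate;
unprotected pairwise testing across 13 tissues would split letters in
most null datasets. Units with fewer than two subjects are excluded from
the comparison with a warning (a single subject has no within-unit
variance).

## Synthetic-data generator

The generator *is* the study design, not a tuning surface: n = 468
individuals; haplotype frequencies (0.621, 0.279, 0.095, 0.005); each
individual the union of two independent gametes (random mating, so
Hardy-Weinberg holds at the haplotype level and the per-locus margins are
0.900 and 0.626); nine traits with baselines set to the published CC-class
LS means and residual SDs back-calculated as SE·√374 from the published
CC-class standard errors (plausible magnitudes, explicitly not published
values); 13 tissues × 3 subjects × 3 technical replicates for Ct tables.
The study does not report its age-class or sire structure, so the
defaults — 3 age classes, 3 dam-age classes, 2 seasons (50/50), 10
sires — are documented choices of a typical station herd, with covariates
independent of genotype (the model's separability assumption); per-level
covariate effects can be injected for confounding experiments. All
randomness flows through numpy's default PCG64 generator with per-table
seed streams derived from one seed, so a fixed seed gives bit-identical
tables across runs and platforms.

What the generator does not emulate: genotyping error, pedigree/kinship
structure (sire families affect only the trait mean, not genotype
sharing), LD decay along a chromosome, selection, or trait correlations
beyond the shared fixed effects. Passing recovery tests therefore
demonstrates estimator correctness under the stated model, not robustness
to those real-data features.

## Problem sizes used in validation

Deterministic reproductions (per-locus table, EM/LD) run on the packaged
468-animal counts. Simulation-based checks use 200 seeds for LS-mean
contrast recovery (±3 SE coverage), 500 replicates for null familywise
error at the 2.78 × 10⁻³ threshold with one F-test per trait × marker
analysis, 1000 random tables for the EM monotonicity sweep, and 100 seeds
for the null expression-letter rate; binomial tolerance bounds
(99.9th-percentile) are applied wherever a nominal rate is checked on a
finite seed set.

## Known limitations

Single-population, few-locus scope; no multi-allelic HWE exact tests, no
F-statistics; fixed-effect sire only; no permutation-based familywise
control; no qPCR efficiency estimation or reference-gene stability
ranking. VCF import is restricted to biallelic SNP records and discards
phase by design.
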