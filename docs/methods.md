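# Methods

## Data model and conventions

All statistics operate on a `GenotypeTable` of biallelic SNPs (diploid
codes 0/1/2, missing = −1) and a `FrequencyTable` of per-population
derived-allele frequencies obtained by polarizing against a designated
outgroup. Internal coordinates are 0-based half-open (BED convention);
VCF I/O converts at the boundary. Missing genotypes are never imputed:
every frequency uses only observed calls, and each statistic carries the
per-site called-allele count n it needs for its finite-sample correction.

The ancestral allele at a site is the allele for which every called
outgroup genotype is homozygous. Sites with a polymorphic or entirely
missing outgroup are flagged unusable and excluded from the D/f3/fd
machinery; they still contribute to π, d<sub>xy</sub> and F<sub>ST</sub>,
which are invariant to polarity.

## Site filters

A site is removed when (i) genotype missingness exceeds 10%, (ii) pooled
minor-allele frequency over non-missing calls is below 0.05, or (iii) a
one-sided exact Hardy–Weinberg test shows **heterozygote excess** at
mid-p < 0.001. The HWE test enumerates the full conditional (Levene)
distribution of the heterozygote count given the allele counts and takes
the upper tail only: in a pooled multi-population cohort a heterozygote
*deficit* is expected (Wahlund effect) and is not evidence of genotyping
error, whereas an excess is the classic signature of collapsed
paralogs/CNVs. This deliberately differs from PLINK's default two-sided
test; the mid-p variant avoids the discreteness conservatism of the
plain exact test. Criteria are evaluated jointly on the input table, so
the filter is idempotent. MAF is computed on the pooled cohort after
missing-call exclusion.

## Diversity and differentiation

With p̂ the (derived) allele frequency from n called alleles, per window
of length L bp:

* π = Σ_sites [n/(n−1)] · 2p̂(1−p̂) / L — exactly the mean pairwise
  difference over all haplotype pairs, without requiring phase;
* d<sub>xy</sub> = Σ_sites [p̂₁(1−p̂₂) + p̂₂(1−p̂₁)] / L;
* Hudson F<sub>ST</sub> as a **ratio of averages**:
  Σ[(p̂₁−p̂₂)² − p̂₁(1−p̂₁)/(n₁−1) − p̂₂(1−p̂₂)/(n₂−1)] / Σ[p̂₁(1−p̂₂)+p̂₂(1−p̂₁)].
  Hudson's estimator is insensitive to unequal and small sample sizes
  (3–18 diploids per population here), and ratio-of-averages avoids the
  instability of averaging per-site ratios. Negative window values are
  preserved — clipping at 0 would bias genome-wide means upward.

The per-bp denominator is the window length, which assumes sites absent
from the table are invariant (true after joint genotyping against a
fixed site set). Windows with no usable site report NaN, never 0.
End-of-contig windows shorter than the window size are flagged partial
and excluded from quantile/Z computations.

LD decay uses the squared Pearson correlation of unphased genotype codes
(Rogers–Huff style) binned by pairwise distance; no haplotype EM, since
phase is required nowhere else in the pipeline.

## D, f3 and the fd scan

Per polarized site, ABBA = (1−p̂₁)p̂₂p̂₃(1−p̂₄) and
BABA = p̂₁(1−p̂₂)p̂₃(1−p̂₄) for the quartet (P1, P2, P3, O);
D = (ΣABBA−ΣBABA)/(ΣABBA+ΣBABA). Significance comes from a delete-one
**weighted block jackknife** (Busing's variance formula) over 1-Mb
genomic blocks weighted by usable-site counts — blocks differ strongly
in informative content, and the weighting keeps the variance estimate
calibrated. |Z| > 3 is the conventional significance rule. f₃(C; A, B) =
mean[(p̂C−p̂A)(p̂C−p̂B) − p̂C(1−p̂C)/(n_C−1)] with the same jackknife;
significantly negative values indicate C is admixed.

The window scan computes, per 100-kb window stepped by 20 kb, the window
D and f_d = (ΣABBA−ΣBABA) / (ΣABBA_D−ΣBABA_D), where the denominator
substitutes the per-site donor frequency p̂_D = max(p̂₂, p̂₃) for both P2
and P3 — the maximal-sharing configuration, which bounds f_d in [0, 1]
when window D > 0. f_d is left undefined for windows with D ≤ 0, a
non-positive denominator, or fewer than 10 informative sites
(ABBA+BABA > 0); low-information windows produce wild ratios and must
not enter the null distribution. Defined values are standardized against
the genome-wide mean and SD (a per-chromosome standardization can be had
by scanning chromosomes separately), converted to one-sided upper-tail
normal p-values, and BH-adjusted. Windows with positive D and q < 0.05
are merged when overlapping or book-ended — on a 20-kb step grid,
consecutive significant windows physically overlap — into introgressed
tracts with mean/max f_d and total introgressed bp.

## Selection scan

Per window: π of the wild cohort, π of the pooled domestic cohort, their
ratio, and Hudson F<sub>ST</sub> between the pooled cohorts. A window is
a candidate when both the π ratio and F<sub>ST</sub> fall at or above
their empirical 90th percentile over defined, non-partial windows
(ties included — deterministic and inclusive). A published fixed cutoff
(such as a realized π-ratio threshold) can be supplied instead of the
quantile; the empirical-quantile default reflects that such cutoffs are
themselves data-dependent deciles. Windows with an undefined value for
either statistic are excluded from both threshold estimation and
selection. Candidates merge into regions; genes are attached by
half-open interval intersection, and two-list overlap enrichment uses
the two-sided Fisher/hypergeometric exact test given a gene-universe
size.

## ILS tract-length null

A tract inherited as ancestral polymorphism through a species split t
generations ago is broken by recombination at rate r per bp per
generation; its expected length is L = 1/(r·t) and its length is modeled
Gamma(shape 2, rate 1/L), giving survival
P(≥ m) = e^(−m/L)(1 + m/L). The default t counts divergence_years/g for
a single branch, reproducing the arithmetic convention of the motivating
analyses; a `two_branches` flag doubles t for the total-branch-length
convention used elsewhere in the literature. Survival probabilities
below the double-precision floor are reported as exactly 0 (with a log
note) — at m/L ≈ 830 the probability is ~10^(−358), far past any
meaningful scale.

## qPCR ΔΔC_T

ΔΔC_T = mean[ΔC_T(target)] − mean[ΔC_T(control)], with ΔC_T the paired
per-replicate difference C_T(segment) − C_T(reference). s₁ and s₂ are
the sample SDs (ddof = 1) of those paired replicate differences and
propagate as s = √(s₁²+s₂²). (Some protocol write-ups call s₁/s₂
"variances" while squaring them again in the propagation formula; the SD
reading is the internally consistent one and is used here.) Relative
copy number 2·2^(−ΔΔC_T) is called deletion below 1.5, normal on the
closed interval [1.5, 3], duplication above 3.

## Synthetic cohorts

The generator is frequency-level, not coalescent: ancestral frequencies
p ~ Beta(0.8, 0.8) (a U-shaped folded SFS), population frequencies
Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes Binomial(2, p).
This gives exact, fast control of the planted truth; msprime serves as
an independent oracle in the test suite, never as the implementation.

Defaults emulate the motivating cohort:

* eight populations at the study's sample sizes (3–18 diploids,
  72 ingroup samples);
* drift F set from the cohort's reported per-bp diversities via
  F ≈ 1 − π_pop/π_ancestral — e.g. F = 0.02 for the high-diversity wild
  ancestor (π ≈ 0.0044), ≈ 0.25–0.30 for bottlenecked domestic breeds
  (π ≈ 0.0032 with breed structure), and 0.80 for the snow-sheep-like
  donor (π ≈ 0.00075);
* ~3 raw SNPs per kb on a 270-Mb three-contig genome, so ~2.5/kb survive
  the MAF filter — the density of the emulated high-quality SNP set;
* one donor→recipient introgression event: 20 non-overlapping tracts
  with exponential lengths (mean 500 kb, truncated at contig ends),
  ≈ 3.7% of the genome, α = 0.5;
* ten 100-kb sweep windows with a 10× heterozygosity reduction in the
  domestic cohort;
* an outgroup emitted as a fixed-allele pseudo-population, carrying the
  derived allele at 5% of sites (d_out) to emulate polarization error.

Inside an introgression tract each recipient haplotype is, independently
with probability α, an ancestry draw from the donor's latent frequency
for the whole tract (tract-level ancestry, not per-site mosaics); the
realized replaced fraction is recorded per tract. Sweeps replace the
cohort's latent frequencies with ones whose per-site heterozygosity is
divided by the reduction factor, pushed toward a fixation side shared
across the cohort (chosen by the pooled frequency) so that pooled
diversity drops as well.

All randomness flows from seed-sequence child streams in a documented
order (base cohort, then one stream per planted event), which makes
output bit-reproducible and planting strictly local: genotypes outside a
planted interval are bit-identical to an unplanted run at the same seed.

What the simulator does **not** emulate: linkage and recombination maps
(sites are exchangeable given frequencies, so haplotype-based statistics
would see no signal), mutation-rate heterogeneity, genotyping error
beyond missingness, a true species tree (populations are a star around
one ancestor — between-population covariance beyond shared ancestral
frequency is absent), and selection dynamics over time. Passing
recovery tests therefore demonstrates the statistical machinery is
correct and calibrated under drift + planted signal, not that real-data
complications are handled.

## Problem sizes and numerical choices

The calibration suite runs 20 null cohorts of 4 populations × 10
diploids with ~50k SNPs on 50 Mb (the fd scan's false-flag rate at BH
0.05 and the rate of spurious |Z(D)| > 3), and one demo cohort as above
for bp-level tract recall/precision and sweep recovery — sizes chosen as
the smallest at which window counts (~2,500 and ~13,500) make the FDR
and quantile machinery meaningful. Window sums use cumulative-sum
prefix differences per contig (O(sites + windows)); the exact HWE test
caches on genotype-count triples; jackknife leave-one-out estimates are
vectorized. Degenerate cases are reported as undefined (NaN) rather than
0 throughout: empty windows, zero F<sub>ST</sub> denominators, fd
gates, and jackknife SEs when fewer than two non-empty blocks exist or
one block carries the entire denominator.
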