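# Methods

## The model

An individual's genome is a mosaic of autozygous (identical-by-descent,
IBD) tracts and outbred background. For an allele at population frequency
*p*, outbred sites carry Hardy–Weinberg genotypes — P(0)= (1−p)²,
P(1) = 2p(1−p), P(2) = p² — while inside an IBD tract both haplotypes are a
single draw: P(2) = p, P(0) = 1−p, and true heterozygotes are absent. Two
consequences drive everything downstream:

1. ROH are detectable as runs of bins depleted of heterozygous sites;
2. rare alleles gain proportionally more homozygotes inside ROH than
   common ones (p versus p², a factor 1/p), so the ROH share of an
   individual's alternate homozygotes, f = g_ROH² / g_total², rises faster
   with ROH coverage G for rare (deleterious) than common (tolerated)
   classes.

The expected relation under this model is
f(G) ≈ G·E[p] / (G·E[p] + (1−G)·E[p²]) per class — concave, saturating
earlier for rarer alleles. The slope contrast between classes is therefore
largest at low coverage and can invert at high coverage; this matters for
experiment design (below).

## ROH calling

Heterozygous sites are counted in consecutive bins of 10 kbp (the grid of
all tracks in the package). Incomplete coverage deflates counts, so each
bin's count is corrected by `bin_size / DP`, DP being the covered bases in
the bin. Bins whose relative coverage falls outside 0.5–2.0× the
individual's genome-wide mean are flagged unusable: their correction factor
is too distorted to trust. A usable bin belongs to an ROH when its
corrected count is ≤ `threshold_factor` (default 0.25) × the individual's
genome-wide mean corrected count per usable bin. We threshold the
*corrected SNP count* — not sequencing depth — because the quantity being
tested is heterozygosity and depth is already absorbed by the correction.
Maximal runs of qualifying bins at least `min_length` = 10 kbp long become
segments; boundaries are bin-aligned (the method is defined on bins, so no
sub-bin refinement is attempted). Unusable bins conservatively break runs
rather than bridging no-data regions; `bridge=k` optionally spans up to k
consecutive unusable bins for cohorts with patchier coverage.

Nucleotide diversity is π = 1000 × Σ corrected counts / Σ usable bases
(het positions per kbp), genome-wide and restricted to usable bins free of
ROH (π-out). π-out ≥ π whenever ROH exist.

## Size classes, sharing, and the null

Classes: S = [10 kbp, short_max), M = [short_max, long_min],
L = (long_min, ∞), defaults 100 kbp and 3 Mbp; ties at the boundaries go to
M on both sides, matching the class definitions "smaller than", "from …
to", "larger than". Alternate threshold pairs (50 kbp/2 Mbp,
150 kbp/4 Mbp) are plain parameters.

Sharing counts, per 10-kbp bin, the number of *individuals* with ≥ 1
overlapping ROH (half-open intersection); a `pairs` mode reports C(n,2)
per bin instead, since the statistic could equally be defined on pairs.
The null redistributes each individual's segments uniformly over the
genome — chromosome chosen proportional to length, position uniform,
resampled on within-individual overlap — preserving the segment count and
the exact multiset of lengths. Placements may cross bin boundaries freely
(lengths are not re-aligned to the grid). Repeating N times gives the null
distribution of any sharing summary; we use the genome-wide maximum.

## Partition tensor and regressions

g[i, j, c, k] counts class-c sites at which individual i carries k
alternate alleles inside ROH class j (S/M/L; R = S+M+L; N = outside).
Assignment is unique because an individual's ROH are disjoint; half-open
intervals make boundary sites unambiguous. Missing genotypes contribute
nowhere; reference homozygotes are tallied under k = 0 but never enter f,
because only alternate alleles carry functional annotations. The nonsense
class is stop-gain/stop-loss; loss-of-function is frameshift/in-frame —
two separate labels.

The stacked OLS model f = β₀ + β₁G + β₂D + β₃GD + ε is fitted by ordinary
least squares (statsmodels); β₂ and β₃ carry two-tailed t-tests for
intercept and slope differences between the D = 0 and D = 1 groups.
Pairwise size-class comparisons use the same model with D = 1 for the
larger class, for all three pairings. Group comparisons between breeds use
Welch's unequal-variance t-test (the safer default when only "two-tailed
t-test" is specified); no multiple-testing correction is applied by
default. Count predictions from fitted lines round half-away-from-zero per
component and compute the net from unrounded components (1568.76×0.1 −
98.67×0.1 = 147.0 → 147), with a flag for the round-then-sum convention.

## Weir–Cockerham F_ST

Per biallelic site, the two-level genotypic variance components (a, b, c)
are computed from per-population sample sizes, allele frequencies and
observed heterozygosity; missing genotypes reduce the per-site sample
sizes. Within a bin, θ = Σa / Σ(a+b+c) over polymorphic sites — the
standard multi-locus ratio of sums, which differs from averaging per-site
ratios and is the stabler combination in sparse bins. θ = 1 exactly for
fixed differences; small negative values are an estimator property and are
kept. 10-kbp tracks are aggregated to 500-kbp windows by missing-aware
means (50 constituent bins, fewer at chromosome ends) before correlating
with sharing. The correlation interface accepts any external 500-kbp track
in the same shape, so phased-haplotype statistics computed elsewhere can be
dropped in; extended-haplotype methods themselves are out of scope.

## The simulator: what it emulates, and what it does not

Defaults emulate a four-population dairy-bull resequencing cohort at desk
scale: 4 populations × 6 individuals on 2 × 15 Mbp chromosomes. Parameters
(all in `SimParams`):

- **Tract plan** (per-individual Poisson counts, uniform length ranges,
  referenced to a 30-Mbp genome and rescaled for other genome sizes):
  S: mean 8 of 15–90 kbp; M: mean 6 of 0.12–0.9 Mbp; L: mean 0.7 of
  3.1–3.6 Mbp. This targets a mean ROH genome fraction ≈ 0.19 with
  individual spread ≈ 0.07–0.4, matching reported cattle cohorts (breed
  means 11.8–24.2%, average 19.5%); Poisson counts supply the
  between-individual variance in G that the regressions require.
- **Site densities** (per bp): synonymous 1.2e-3, non-deleterious 8e-4,
  deleterious 2.5e-4, nonsense/LoF 2e-5 each — scaled down from
  genome-scale SNP densities so that out-of-ROH heterozygosity is ~6–7 het
  sites per 10-kbp bin, enough for reliable per-bin calling. Consequently
  π (~0.7/kbp) is lower than real sequencing cohorts (~1.6–1.9/kbp) by
  design; only contrasts, not absolute densities, transfer.
- **Allele-frequency laws**: Beta distributions per class with means 0.3
  (synonymous), 0.2 (non-deleterious), 0.05 (deleterious, nonsense, LoF).
  The rarity ordering is the substantive assumption; the exact spectra are
  stated parameters, not claims about cattle.
- **Depth model**: per-bin covered fraction = min(1, LogNormal(−σ²/2, σ)),
  σ = 0.15, with a 5e-4 chance of a severe-dropout bin (covered fraction
  ×0.05–0.45). This yields one or two clearly unusable bins per genome —
  enough to exercise the caller's usability window without fragmenting
  long tracts, whose detection the cohort is meant to support.
- **Error rates**: truly homozygous sites read as heterozygous at 1e-3;
  genotypes missing at 2e-3.
- **Sweep option**: a fixed interval carried as an identical tract by a
  fraction of individuals (default 0.8), with strong allele-frequency
  divergence of one population inside it — the positive control for
  sharing hotspots and the sharing/F_ST correlation.

Not modelled: recombination, linkage disequilibrium beyond the planted
tracts, phasing, coalescent demography, per-variant fitness effects, or
class-specific selection by tract age. Passing tests therefore demonstrate
the correctness of the statistics under the p-vs-p² autozygosity law and
uniform tract placement — not robustness to LD structure, variant-calling
artifacts, or reference bias in real data.

### Enrichment experiment conditions

The β₃ > 0 contrast (deleterious vs non-deleterious slopes) is tested under
`enrichment_experiment_params`: 20 individuals, short and medium tracts
only (coverage ~0.02–0.35, the steep region of the saturating f–G curve)
and a deleterious density of 2e-3/bp so each individual's f_d rests on
enough homozygotes. At high coverage the concavity of the rare-allele
curve can flatten or invert the contrast, so a cohort dominated by heavily
autozygous genomes is the wrong instrument for this measurement.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open throughout; VCF emission converts to
  1-based.
- f proportions with zero denominators (no alternate homozygote of a
  class) are missing (NaN), never 0, and are dropped pairwise from
  regressions with the count reported.
- Zero-variance inputs: Pearson r is missing; Welch's test returns
  t = 0, p = 1 when both groups are constant and equal.
- Rank-deficient regression designs (e.g. constant coverage) raise rather
  than returning unstable estimates.
- Tensor identities (g_R = g_S + g_M + g_L, g_N = g_total − g_R,
  f_S + f_M + f_L = f_R) hold exactly by construction and are asserted to
  1e-12 in tests.
- Tract and null placement resample on overlap with a retry cap (200 and
  1000 respectively) and raise naming the individual when packing fails.

## Problem sizes

Tests and the acceptance script run on 30-Mbp genomes with 20–24
individuals (~70–120k sites), 200 randomization-null replicates for the
sweep control, 500 replicates for CI-coverage calibration, and 10 replicate
cohorts × 60 nulls for null calibration — sizes chosen so the whole suite
exercises every stage end-to-end in a few minutes on one CPU while keeping
Monte-Carlo errors well inside the asserted margins.

## Known limitations

- The caller's "0.25× genome coverage" threshold is interpreted as 0.25 ×
  the mean corrected het count per usable bin; thresholding raw counts or
  depth are alternative readings, reproducible via `threshold_factor` and
  the correction pathway.
- Sharing of ROH is individual-count based by default; pair counts are a
  flag away, as the statistic admits both definitions.
- Reported absolute values (π, ROH counts) are functions of the synthetic
  densities and are not calibrated to any real cohort; directional and
  structural results (enrichment signs, identities, estimator properties)
  are the tested claims.
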