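# Methods

## The inference problem

In species with young, homomorphic sex chromosomes, the sex-linked region
(SLR) is invisible to karyotyping and must be found by contrasting the
genomes of phenotypic males and females. Three signatures identify an
XY-type SLR:

1. **Genetic differentiation** — at X/Y-differentiated sites every female
   (XX) is homozygous while XY males are heterozygous, producing an
   allele-frequency contrast between the sexes and elevated F_ST.
2. **Coverage bias** — Y-specific (hemizygous) sequence recruits reads
   only from males, so the male:female depth ratio diverges.
3. **Genotype pattern** — the site-level XY pattern itself (all females
   fixed for one homozygote, males heterozygote-enriched) can be screened
   directly and turned into per-individual scores.

A complication this package models explicitly: phenotypic males need not
be genetically homogeneous. A cohort can contain a class of males (here
"M1") whose Y haplotypes are weakly differentiated and largely X-like —
plausibly products of occasional X–Y recombination — alongside strongly
differentiated "M2" males carrying a divergent Y. M1 males dilute any
all-male-vs-female contrast; the decisive scans therefore contrast females
against the M2 class once it is identified.

## Statistics

**Per-site F_ST.** Weir & Cockerham (1984) variance components for two
groups (r = 2): with per-group sample sizes nᵢ, alt-allele frequencies pᵢ
and observed heterozygote frequencies hᵢ, the estimator decomposes
variance into among-group (a), among-individual-within-group (b) and
within-individual (c) components; F_ST = a/(a+b+c). Missing calls are
excluded from group counts; sites where a group has no call, or where
n̄ ≤ 1, are undefined. Negative per-site estimates are a finite-sample
property and are retained. Windowed F_ST defaults to the ratio-of-sums
Σa/Σ(a+b+c) ("weighted"); mean-of-ratios is available because either
convention appears in published scans.

**Coverage ratio.** Per window: `log2(mean male depth + 0.01) − log2(mean
female depth + 0.01)`. The 0.01 pseudocount keeps zero-coverage windows
finite; a fully hemizygous window at 16× male depth scores
log2(16.01/0.01) ≈ 10.6, and the hemizygous-region threshold of 3
corresponds to an ≥ 8-fold male excess.

**SNP density.** A locus counts for a sex when it is polymorphic among
that sex's called genotypes (both alleles observed; an alt-carrier variant
is available by config). Densities are per Mb; the ratio uses the same
pseudocount.

**Candidate-SLR calling.** The window threshold is the empirical quantile
(linear interpolation between order statistics, the numpy default) of
non-missing windowed F_ST — 0.99 by default, computed genome-wide (a
per-chromosome scope is available). Flagged windows separated by at most
one unflagged window merge; merged runs need at least two flagged windows.
The merge/min-run parameters are artifact additions that replace visual
inspection of Manhattan plots; on small test genomes where the planted SLR
occupies several percent of all windows, the quantile should be matched to
that geometry (the examples and tests use 0.92 on 12 Mb toy genomes and
0.99 at the default 120 Mb scale).

**Locus classification.** XY-like: ≥ 3 called samples per sex, all called
females share one homozygous genotype, and the male heterozygote fraction
is ≥ 0.5 (configurable; no published cutoff exists for the enrichment, so
0.5 — "most males" — is the default). XY-strict additionally requires
every called male heterozygous; ZW-strict swaps the sexes. All criteria
depend only on homozygote/heterozygote status, hence are invariant to
REF/ALT relabelling.

**Sex-linkage scores.** A locus panel is classified a priori from a
defining contrast (females vs M2 males) restricted to one region. Every
individual's score is n_het/n_called over panel loci. Defining females
score exactly 0 — a structural identity, since panel membership requires
them to be fixed homozygous — which the test suite asserts on every
simulated cohort. Scores from two panels are dichotomized (≥ 0.6 for the
large panel, ≥ 0.3 for the small degenerate one) and tabulated 2×2; the
two-sided Fisher exact test (hypergeometric enumeration, as implemented in
scipy) and a Spearman correlation on the raw scores (t-approximation for
the p-value; exact ±1 maps to p = 0) quantify co-occurrence. Individuals
with no called panel locus are excluded pairwise.

**LD.** r² is the squared Pearson correlation of alt-allele dosages
(composite LD) with pairwise deletion — deterministic and phase-free,
though not identical to haplotype-frequency r² from EM-based tools.
Expected background r² is 1/(n−1), so comparisons between groups of
different size are biased; the tests compare matched group sizes. LD
pruning is greedy within sliding windows of 50 SNPs advancing by 10: of
any pair with r² > 0.2, the member with more missing calls (tie: the
later position) is removed, and passes repeat until stable so the filter
is idempotent.

**Change-points.** Greedy binary segmentation on within-segment sum of
squared deviations (the Gaussian mean-change cost up to constants), ties
broken leftmost, minimum segment two windows. Stopping is either a fixed
number of change-points or an SIC-style rule (stop when the SSE reduction
falls below log n) — an approximation to the reference implementation's
default penalty, which is not otherwise specified for this analysis.

**Structure.** PCA standardizes dosages by √(2p̂(1−p̂)) with per-locus
mean imputation of missing calls (monomorphic loci are skipped), takes
left singular vectors scaled by singular values, and fixes signs so each
component's largest-magnitude loading is positive. IBS distance is
1 − shared alleles/(2 × co-called loci). Neighbor joining is Saitou–Nei
with lowest-index tie-breaking; negative branch lengths are clamped to 0
with the deficit moved to the sibling branch. Male classes: score rule
(sex-linkage score ≥ 0.6 ⇒ M2) by default; alternatively exact 1-D
2-means on PC1 of SLR SNPs, labelling the cluster nearer the female
centroid M1.

## The simulator

`simulate_cohort` draws, from a single seed:

- **Cohort** — default 5 females + 12 M1 + 5 M2 males (the informative
  population structure described above); any composition is configurable.
- **Autosomal background** — SNPs at 5/kb with Beta(0.8, 0.8) alt-allele
  frequencies, genotypes under Hardy–Weinberg identically for both sexes.
  5/kb is a desk-scale stand-in for the raw density of a vertebrate
  resequencing call set (~13/kb) after quality filtering; what matters for
  the scan geometry is that background windows carry a few hundred sites,
  which keeps window-level F_ST noise well below the SLR signal.
- **XY-differential intervals** — extra SNPs at 2/kb (the dense, strongly
  differentiated SLR) or lower (the small degenerate segment). Per locus,
  females are fixed for one homozygote (0/0 or 1/1 with equal odds —
  exercising REF/ALT-flip invariance), M2 males are heterozygous, and M1
  males carry the female genotype with probability `m1_y_similarity`
  (default 0.95, chosen to land M1 scores near the observed ~0.05 level;
  no direct measurement of this quantity exists).
- **Y-hemizygous segments** — M2-male-only sequence: female and M1 depth 0
  (plus an optional uniform noise floor, default 0), M2 depth like any
  window; no SNPs are planted there, since females have nothing to
  genotype against. The ~10.6 log2 ratio arises from the pseudocount
  formula, not from a hard-coded ratio.
- **Depth** — per (window, sample), a unit-mean gamma multiplier with
  variance `depth_dispersion` (0.02) scales the 16.1× mean, and read
  counts are Poisson at that rate (150 bp reads). This reproduces
  overdispersed window depth without read-level simulation.
- **Noise** — genotype calls flip to a uniformly chosen different code
  with probability 0.001 and go missing with probability 0.02.

Default geometry: chr2 (40 Mb) + chr6 (80 Mb) = 2,400 windows of 50 kb,
with a 2 Mb XY SLR on chr6 (30–32 Mb), a 100 kb XY segment (chr2
20.0–20.1 Mb) and a 200 kb hemizygous segment (chr2 20.1–20.3 Mb), all
window-aligned. The SLR is ~1.7% of windows, comparable to the share a
~40 Mb SLR occupies in a multi-Gb genome, so the top-1% rule flags most of
it.

**What the simulator does not model:** linkage/recombination structure in
the autosomal background (sites are independent), mapping artifacts,
reference bias, indels and multi-allelic sites, population structure
beyond the two Y classes, and read-level noise. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
assumed generative model, not robustness to alignment-level pathologies of
real resequencing data.

## Pipeline composition

`run_pipeline` chains: MAF/missingness filter (defaults 0.05 / 0.25) →
window tracks and SLR calling — computed on the female-vs-M2 contrast
whenever the sample sheet labels M2 males, because M1 males dilute the
sexes' allele-frequency contrast — → locus classification → coverage
markers → score panels (one per chromosome: the best F_ST candidate, or,
for a chromosome whose SLR is visible only as Y-specific coverage, the
male-specific region padded by two windows to capture flanking XY loci) →
scores and the co-occurrence test → change-point diagnostics → LD-pruned
genome-wide PCA, NJ tree on panel loci, male-class assignment. The summary
JSON embeds a provenance block (config hash, seed, package version) and is
byte-deterministic for a fixed config.

## Numerical choices and edge cases

- Quantile method: linear interpolation (numpy default); no variant is
  prescribed anywhere, and the choice moves the threshold by less than one
  order statistic.
- Sites with a+b+c = 0 (e.g. both groups fixed for the same allele) are
  excluded from window aggregation rather than treated as 0.
- `pairwise_r2` guards monomorphic loci with a 1e-9 variance tolerance
  against float residue in the sums-of-squares form.
- Empty panels produce warnings and NaN scores, which co-occurrence
  excludes pairwise; a 2×2 test on fewer than 3 paired samples reports
  NaN for Spearman.
- Binary segmentation requires a strict (> 1e-12) SSE reduction, so a
  constant series yields a single segment.
- Half-called VCF genotypes (./0) are missing; phase is ignored.

## Known limitations

- The consistency/classification screens recover the *rule*, not the
  planted truth per se: in a finite cohort a handful of background loci
  genuinely exhibit the XY pattern by chance (≈ 1e-5 per locus for a
  5F/5M contrast), so "exact recovery" tests assert recall 1 plus
  pattern-verified extras.
- Windowed F_ST of an all-male-vs-female contrast is strongly diluted
  when most males are M1-like; on small genomes this pushes the SLR below
  the background quantile. This is a property of the contrast, not the
  estimator — the pipeline's F-vs-M2 scan is the supported remedy.
- NJ and pairwise-r² matrices are O(n²) and intended for region-scale
  locus sets and cohort-scale sample counts, not genome-wide all-pairs
  computation.
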