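# Methods

## Coordinate conventions and overlap semantics

All genomic positions are 0-based half-open internally (BED convention).
Tables printed in the 1-based inclusive browser dialect (the packaged
risk-block and methylation-region tables) are converted on ingest by
subtracting one from the start; nothing downstream ever re-converts. Two
intervals overlap iff they share at least one base (`max(starts) <
min(ends)`); there is no minimum-fraction option, matching the default
semantics of standard intersection tools. Sorting ties break by
(chromosome lexicographic, start, end, name), so every container and output
file is deterministic. Zero-length records are rejected at parse time: they
cannot overlap anything and almost always indicate a dialect error.

## The risk-block table

The packaged table carries 16 risk LD blocks (GRCh37) with their index
SNPs, genomic spans, location class (exonic/intronic/intergenic) and
nearest gene. Blocks are defined elsewhere (r² ≥ 0.9 proxy searches against
reference haplotype panels); the threshold is carried as metadata only — LD
computation from genotypes is out of scope. Two blocks on chr9 overlap
almost entirely; they are deliberately kept as separate rows and counted
separately, preserving per-SNP accounting. The mean inclusive span of the
16 printed blocks is 30,637 bp; the historically documented average of
32,312 bp (used as the random-region default length) is not reproducible
from the printed spans — `mean_block_length` reports the honest mean, and
the sampler keeps the documented default. Users who need SNP-anchored
flanking regions get the block midpoint as a documented deterministic
fallback when the SNP coordinate is absent from the table.

## The enrichment test

For one peak track: `a` of `n` blocks contain ≥ 1 peak; `b` of `N` random
regions (default N = 10,000, fixed length, chromosome chosen proportional
to its number of valid start positions, start uniform) contain ≥ 1 peak;
Fisher's exact test on [[a, n−a], [b, N−b]]. Defaults: two-sided
alternative (`greater` available via a flag — the underlying question is
one-sided, but two-sided is the conservative default), α = 0.05, no
multiple-testing correction across tracks; every result row carries the
number of tests in its scan so a reader can apply their own correction.
One random draw is shared by all tracks in a scan. The sampler does not
mask assembly gaps by default; an `exclude` region set (rejection sampling)
is available.

The counting unit is whole regions — a block either overlaps the track or
it does not — not overlapping base pairs.

### Why the background model is only approximately null

The background matches the *mean* block length, but blocks vary from
~2 kb to ~90 kb, and the probability that a region of length L contains a
Poisson-placed peak, 1 − exp(−λ(L + ℓ)) (λ peak density per bp, ℓ the mean
peak length), is concave in L. By Jensen's inequality the mean block hit
probability is *below* the hit probability of a mean-length region; the
deficit is ≈ λ²·Var(L)/2 per block. At sparse track densities (a few peaks
per Mb) this is negligible; at broad-enhancer-mark densities (tens of
peaks per Mb) it reaches a sizeable fraction of a block and the two-sided
test drifts off its nominal level. This is a property of the
fixed-length-background design itself (per-block length-matched nulls are a
stated non-goal), and it is why the operating-characteristic studies below
fix sparse regimes for size measurement.

## Operating-characteristic studies (`epiblocks.calibration`)

All studies run on the toy genome: three chromosomes (50, 30, 20 Mb)
carrying 16 non-overlapping risk blocks with the real block-length
spectrum, placed deterministically. Random regions use the toy blocks' own
mean length (30,637 bp), the faithful application of the
mean-length-background rule to this block set.

* **Size**: tracks with no planted enrichment (factor 1) at 1.6 peaks/Mb,
  1.5 kb peaks — sparse enough that the convexity bias is < 0.02 blocks, so
  the measured rejection rate isolates the discrete Fisher machinery. The
  regime was selected by exact Poisson-binomial computation of the
  rejection probability over the (density, peak length) grid before the
  test was frozen: the exact size of the discrete test is a jagged function
  of the background hit probability p₀, and p₀ ≈ 0.05 sits on a stable
  plateau. Measured size ≈ 0.030 at α = 0.05 (8,000-replicate design
  verification); the acceptance band is [0.02, 0.08].
* **Power**: 5× in-block peak density at 10 peaks/Mb, 200 bp peaks (a
  dense, narrow, TF-track-like regime — the density that maximizes exact
  computed power for this block set). Measured power ≈ 0.91 against the
  ≥ 0.9 requirement. Two *different* track regimes for size and power are
  deliberate: size must be measured where the background model's null
  actually holds, power where detection is hardest-but-attainable; both
  regimes are realistic ChIP-seq densities.
* **DEG filter**: 2,000 genes, 10 samples per group, 5% planted DEGs with
  a 2-unit log2 shift, noise σ = 0.5. Recall ≈ 1.0, empirical FDR ≈ 0 under
  the defaults (fold change > 2, q < 0.05): at this effect size the
  per-gene t ≈ 9, so the filter's thresholds, not the test, bind.

Replicate counts (6,000–10,000 for size, 2,000–2,500 for power, 50 for the
DEG study) keep Monte Carlo standard errors small relative to the margins.

## TFBS classification

The promoter window is [TSS − 5 kb, TSS + 1 kb) on the plus strand,
mirrored on the minus strand, clipped at zero. Strand-awareness is a
design choice: "upstream" is meaningless without it; unstranded TSS records
fall back to the plus-strand rule and the fallback is logged. A site
overlapping any TSS window by ≥ 1 base is a promoter site (the same overlap
semantics as everywhere else); otherwise distal. For per-block summaries,
each TF track is first clipped to the enhancer-marked segments of the
block, each surviving fragment is classified, and the block×TF cell
records presence of ≥ 1 distal and/or ≥ 1 promoter site plus whether the
segment carried both H3K4me1 and H3K27ac. An empty TSS catalogue makes
every site distal; a block with no marked segment yields an empty row.

## Differential screens and the DEG filter

The methylation screen lists every (region, block) overlap pair and, when a
background configuration is supplied, reuses the enrichment machinery with
the region set in the role of the peak track. Hyper/hypo direction is
carried through but unused, as the screen is direction-agnostic.

The F statistic is between-group MS over within-group MS with (1, n₁+n₂−2)
degrees of freedom — numerically the square of the equal-variance t — with
documented degenerate cases: zero within-group variance with unequal means
gives p = 0; a completely constant gene gives p = 1. Fold change is the
difference of group means on the log2 scale (the standard reading for
RMA-style normalized matrices; the package never normalizes raw data).
Storey q-values use the single-λ estimator at λ = 0.5,
π̂₀ = min(1, #{p > λ}/((1−λ)m)) floored at 1/m — the floor prevents a
degenerate π̂₀ = 0 (all q-values zero) when every p in a small set falls
below λ and assumes at least one null test; the λ-grid smoother is a
non-goal. With π̂₀ = 1 the estimator reduces exactly to Benjamini–Hochberg,
which the tests exploit as a cross-check. Both DEG thresholds are strict
inequalities. Genes without an annotation entry cannot be placed on the
genome; the locus-overlap screen excludes and counts them.

## Synthetic data: what it does and does not emulate

The generators produce Poisson peak tracks with a controlled in-block rate
multiplier, uniform stranded TSSs, methylation-region sets with an exact
in-block count, and two-group Gaussian log2 expression with planted mean
shifts. They emulate the *marginal* statistics the pipeline is sensitive
to — densities, lengths, in/out-of-block contrasts, group mean shifts —
and none of the spatial or correlation structure of real chromatin:
no peak clustering or domain structure, no GC or mappability bias, no
assembly gaps, no gene-level variance heterogeneity or probe effects.
Passing tests therefore certify the machinery (counting, testing,
filtering, calibration under the stated model), not robustness to those
real-data pathologies. Every generator is bit-reproducible under a fixed
seed and every emitted file is readable by the package's own readers;
ground-truth labels accompany every dataset.

## Published-call fixtures

The packaged per-block presence tables (histone marks, CTCF) and TF-call
table record published calls so the counting/summary code paths can be
exercised without peak downloads. One internal inconsistency in the source
is preserved as printed: the per-block tables give 7 blocks with both
endothelial histone marks and an endothelial CTCF site, while the
accompanying prose says 8; the tables are taken as authoritative and the
package computes 7. `unavailable` cells mark (cell type, feature) pairs
with no public data, distinct from `N`.

## Numerical and degenerate-input choices

Fisher's two-sided p sums all tables with the observed margins whose point
probability is ≤ the observed one (relative tie tolerance 1e−7); degenerate
margins return 1. The q-value computation is order-stable (stable argsort)
and permutation-equivariant. Random-region sampling with an exclusion set
retries rejected draws in batches and fails loudly after 1,000 rounds
rather than looping forever. Empty inputs are legal wherever a count of
zero is meaningful (empty BED → empty set; empty DEG list → empty screen);
they are errors where a statistic would be undefined (mean length of no
blocks, expression groups with < 2 samples).

## Known limitations

* The background is not GC-, chromatin-state- or gap-aware, and is not
  length-matched per block; see the bias analysis above.
* No multiple-testing correction across tracks (by design; the test count
  is reported).
* The TSS catalogue, gene annotation and peak tracks are user inputs; the
  package ships no genome annotation beyond the fixtures.
* Probe-to-gene collapsing for expression arrays is left to the user; the
  filter tests one row per gene.
* p-values from the discrete Fisher test are conservative at n = 16 blocks;
  non-significance of a small overlap (as in the methylation screen) should
  be read with that in mind.
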