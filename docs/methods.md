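# Methods

## Overview

`poolsweep` analyzes pooled resequencing (pool-seq) data from divergent
artificial-selection experiments. The pipeline runs from per-site pooled
allele counts to: (i) windowed pairwise F_ST between two population pools,
(ii) empirically thresholded *differentiated regions*, (iii) a
heterozygosity-based *duality* classification of those regions (which line
carries a fixed extended haplotype), and (iv) *adjusted allele frequency*
(adjAF) matrices that expose haploblock mosaics. A forward simulator of
bidirectional truncation selection on standing variation provides
ground-truthed inputs for every stage.

## Per-site statistics

Sites are reduced to the two most frequent nucleotides pooled across all
population pools (ties broken alphabetically); the shared minor allele's
read frequency p̂ = a/n is the per-pool allele frequency, where n counts
major + minor reads only (N and deletion classes are carried through I/O
but excluded from frequency math). Expected heterozygosity is H = 2p̂(1−p̂)
with no finite-pool correction, so H ∈ [0, 0.5]. A site is a SNP when the
pooled minor-allele count is at least `min_count` (default 3). A site is
coverage-valid for a pool when its total depth lies in
[`min_cov`, `max_cov`] = [10, 100].

Between-pool differentiation uses the per-site two-pool components

    h_i = a_i (n_i − a_i) / (n_i (n_i − 1))
    N   = (a_1/n_1 − a_2/n_2)² − h_1/n_1 − h_2/n_2
    D   = N + h_1 + h_2

with window F_ST the ratio of sums ΣN/ΣD over the window's SNPs. N is an
unbiased estimator of the squared frequency difference net of binomial
sampling, so neutral same-frequency pools have E[ΣN] = 0 and window F_ST
is not clamped when it comes out slightly negative — clamping would bias
the downstream empirical quantile.

Windows are 1 kb with 50% overlap on a fixed grid anchored at position 1;
only full-length windows are emitted. A window is valid when its covered
fraction reaches `min_fraction` (default 1) and ΣD > 0. The covered
fraction's denominator is configurable: `"sites"` (default) counts only
positions present in the count table, the right choice for sparse
sites-only tables such as simulator output; `"positions"` divides by the
window size for dense all-sites tables.

## Differentiated regions

The F_ST threshold is the empirical top-5% cut over *valid* windows:
the smallest observed value such that at most `floor(0.05 n)` windows lie
strictly above it; windows qualify when F_ST is strictly above the
threshold, so boundary ties never qualify. Qualifying windows merge into
one region when the gap between their outer coordinates is under 100 kb
(overlapping windows union first). Clusters with fewer than 2 SNPs or
shorter than 100 kb are dropped. For every surviving region the per-pool
mean and median site H are computed over coverage-passing sites in the
span. Regions longer than 0.5 Mb are classified by duality: a line is
"fixed" when its regional mean H ≤ 0.1 (boundary inclusive), giving
`fixed_high`, `fixed_low`, `fixed_both`, or `neither`; shorter regions are
`unclassified`. Regions carry a `score` (summed member-window F_ST); when a
single "top" region is needed, regions are ranked by length with score as
the tie-break — the longest coherent region is the natural worked-example
candidate.

Decisions taken where the procedure was underdetermined: the threshold is
computed over valid windows only; region spans extend to window edges, not
SNP edges; the ≥2-SNP filter uses the same pooled-minor-count SNP
definition as the window statistics; coverage validity for a pairwise
F_ST window considers only the two compared pools.

## Polarization (adjAF)

Within a region, the reference pool is the one with the lowest regional
mean heterozygosity ("lowest haplotypic complexity"; ties broken by
declared pool order) — in practice a pool carrying one fixed extended
haplotype, with frequencies near 0 or 1. At every site where the reference
frequency is strictly above 0.5 the frequencies of all pools are flipped
to 1 − AF; sites with undefined reference frequency stay unflipped and
are flagged. The transform is idempotent and preserves |p̂_i − p̂_j| at
every site. Window means use a non-overlapping 5-kb grid anchored at the
region start. Haploblock segmentation (runs of ≥3 windows all ≤ 0.1
"shared" or all ≥ 0.4 "divergent") is a labeling heuristic for display,
off by default.

## Forward simulator

The generative model mirrors a bidirectional selection experiment founded
from a cross of partially inbred lines:

* **Deep ancestry.** Seven ancestral haplotypes are related through
  shared-ancestry tracts (exponential lengths, mean 15 kb) in which they
  collapse to 2–3 distinct local variants; within a tract, each site's
  derived allele is carried by a random proper subset of the local
  variants. Two ancestral haplotypes are therefore identical over long
  stretches and divergent over others — the substrate of the haploblock
  mosaics seen in polarized frequencies, with shared segments in the
  tens-of-kb range.
* **Founder sublines.** Seven sublines each carry two mosaic haplotypes
  assembled from the ancestral set with 3600 historical crossovers in
  total (~25 kb mosaic segments); the ancestral "painting" of every
  subline haplotype is recorded as ground truth. The founder population
  (census 150 per line) takes balanced crosses of the sublines.
* **Trait and selection.** The trait is additive over a small set of
  causal loci plus Gaussian environmental noise scaled so founder
  heritability is h² = 0.5 (the response curve constrains h² only
  loosely; 0.5 is a standard default for an 8-week body-weight-like
  trait). Each generation the top (high line) or bottom (low line) half
  of the census is selected by truncation.
* **Mating.** Two systems: `wright_fisher` draws each offspring gamete
  from an independently, uniformly chosen parent — drift is then exactly
  binomial, E[ΔAF] = 0, Var(ΔAF) = p(1−p)/2N, and E[H_t] = H₀(1−1/2N)^t
  without selection (this idealization permits occasional selfing and is
  the calibration mode). `equalized` (default) makes the selected parents
  contribute as equally as possible to the gamete pool, emulating a
  breeding scheme structured to minimize inbreeding and stochastic
  fixation; diversity then decays more slowly than iid Wright–Fisher at
  the same parent count, which is what keeps two thirds of large
  differentiated regions segregating in one line after 55 generations —
  the observed regime. A `balanced` transmission mode (every parent
  contributes two complementary gametes) conserves allele frequencies
  exactly and serves as the no-drift limit.
* **Recombination.** Uniform 3 cM/Mb per chromosome (macrochromosome-like);
  crossover counts are Poisson per meiosis. A `free_recomb` switch makes
  sites unlinked for calibration runs.
* **Demography.** 55 selected generations; snapshots at generations 40 and
  55; relaxed sublines branch at generation 44 and drift for 9 further
  generations. Six pools are sequenced by default (HWS55, LWS55, HWS40,
  LWS40, HWR9, LWR9), 30 individuals each except one 9-individual pool
  (LWS40), emulating the asymmetric small pool in the real design.
* **Sequencing emulation.** Per pool and site, `pool_size` individuals are
  sampled without replacement; depth is Poisson(30) clipped to [10, 100];
  reads are binomial in the pool sample frequency; each read miscalls to a
  uniformly chosen other base with probability 0.005; and 1.5% of reads
  derive from the cross-pool mixture (index misassignment / mapping noise).
  The contamination term matters qualitatively: without a noise floor,
  divergently fixed windows give F_ST of exactly 1.0 and the empirical
  quantile degenerates onto that point mass, a behaviour real pooled data
  do not show.

### Planted scenarios

`plant_sweep_scenarios` designates one scenario per chromosome:

* **duality** — a large (+3) effect on a single low-frequency founder
  haplotype. The carrier additionally receives introgression-like tracts
  (gamma-distributed lengths, mean 30 kb, ~40% genome coverage, 80%
  private-allele density inside tracts) in which its alleles are private
  to it, so roughly a quarter of the chromosome's sites are divergent
  between the carrier and every other haplotype — the configuration the
  worked-example QTL region exhibits (about 28% of its positions highly
  divergent between the lines). The high line is expected to fix the
  carrier (regional mean H ≤ 0.1) while the low line keeps segregating.
  The designated span is the carrier's whole chromosome.
* **opposed** — two founder haplotypes with equal-and-opposite (+3/−3)
  effects at nearby private sites; each line sweeps its own haplotype and
  the region is expected `fixed_both`.
* **neutral** — a region (and, by designation, its whole chromosome) free
  of causal loci, expected to stay below the empirical F_ST threshold
  under drift alone.

Background polygenic loci (4 by default, exponential effect sizes of mean
0.25, random signs) are placed outside scenario regions and never on a
neutral-designated chromosome.

### Default scale and calibration

The default genome is 2 × 2.5 Mb with 80,000 segregating founder sites
(~16/kb raw; ~8 SNP/kb after within-experiment fixation, matching the
site density the worked-example region reports: 36,934 sites in 4.4 Mb).
Census 150 with half selected gives ~75 breeding parents under equalized
contributions; neutral-region heterozygosity then decays over 55
generations to roughly 40–60% of its founder value, consistent with
selected lines that still segregate in most of the genome while drifting
to fixation in a minority of regions. The pure-drift calibration
configuration (census 35, no selection, iid Wright–Fisher mating, exact
founder frequencies, unlinked sites) reproduces E[H_t] = H₀(1−1/2N)^t to
within Monte-Carlo error and is the setting used for the drift-decay and
neutral-false-positive checks.

### What the generator does and does not emulate

It emulates: founder haploblock mosaics with realistic shared-segment
scales, line-specific fixation at selected loci, hitchhiking over
Mb-scale extents, relaxed sublines, finite-pool sampling, depth variation
in the 10–100× band, sequencing error and a cross-pool contamination
floor. It does not emulate: mapping and alignment artifacts beyond a flat
noise floor, indels and structural variation, mutation during the
experiment, sex chromosomes, overlapping generations, family structure
beyond equalized contributions, or the low line's physiological selection
plateau. Passing tests therefore demonstrate the pipeline's correctness
and its behaviour under a faithful-but-idealized generative model; they do
not certify performance on real aligned data, where filtering and mapping
artifacts dominate the error budget.

## Numerical choices

* Frequency tie-breaks in biallelification follow alphabetical base order.
* The empirical threshold is an order statistic, not an interpolated
  quantile; degenerate all-equal inputs yield that value and strict
  qualification selects nothing.
* Invalid windows carry NaN F_ST (never 0); NaN is ignored by the
  threshold and all summaries.
* Gap arithmetic is exact integer work on 1-based inclusive coordinates;
  the single 0-based conversion lives in the BED writer.
* Simulation is deterministic given the config seed (one generator drives
  site layout, founders, reproduction and sequencing in a fixed order).

## Problem sizes used in the shipped checks

Estimator and clustering oracles run on 10⁴ random count quadruples and
500 random window sets. Drift calibration uses 20 replicate populations
of 50 unlinked sites (N = 35, t = 55). The neutral-region control and the
planted-sweep recovery each run 25 seeded replicates at, respectively,
2 × 1.5 Mb / 24k sites and the default 2 × 2.5 Mb / 80k sites. These sizes
keep a full run in the minutes range on one CPU while leaving Monte-Carlo
error well inside the margins being tested.

## Known limitations

* The duality signature's recovery rate depends on the founder mosaic
  scale relative to the fixed 100-kb clustering gap; haploblock structure
  much coarser than ~50 kb fragments called regions.
* Window F_ST above ~0.95 requires near-monomorphism of both pools within
  the window; a region's *mean* heterozygosity can exceed 0.1 while every
  *qualifying* window inside it is locally fixed. Region-level summaries
  should always be read together with the window tracks.
* The equalized-contribution mating model raises effective size above the
  iid-Wright–Fisher value for the same census; users wanting a specific
  realized N_e should calibrate census against observed heterozygosity
  decay, as done here.
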