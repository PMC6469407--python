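# poolsweep

Selective-sweep analysis of pooled resequencing (pool-seq) data from
divergent artificial-selection experiments — and a forward simulator of
such experiments for validating every stage against ground truth.

## The problem

Long-term bidirectional selection experiments (the motivating system is a
pair of chicken lines selected up and down for juvenile body weight for 55
generations from a common founder population, plus relaxed sublines) leave
two intertwined genomic signatures: allele-frequency differentiation
between the lines, and loss of heterozygosity where a haplotype sweeps to
fixation. With pooled sequencing of 9–30 individuals per line, neither
individual genotypes nor phase are available — all inference runs on
per-site read counts.

`poolsweep` implements the full count-level workflow:

1. **Windowed pairwise F_ST.** Per site, pools are reduced to a shared
   major/minor allele pair; with minor count *a* of depth *n* per pool and
   *hᵢ = aᵢ(nᵢ−aᵢ)/(nᵢ(nᵢ−1))*, the per-site components are
   *N = (a₁/n₁ − a₂/n₂)² − h₁/n₁ − h₂/n₂* and *D = N + h₁ + h₂*; a
   window's F_ST is ΣN/ΣD over its SNPs (1 kb windows, 50% overlap,
   pooled minor count ≥ 3, per-pool depth in [10, 100], coverage
   fraction 1).
2. **Differentiated regions.** Windows above the empirical top-5% F_ST
   threshold are clustered when less than 100 kb apart; clusters with
   < 2 SNPs or < 100 kb are dropped; per-line mean/median heterozygosity
   (H = 2p̂(1−p̂)) summarizes each region.
3. **Duality classification.** Regions > 0.5 Mb are classed by which line
   is close to fixation (mean H ≤ 0.1): `fixed_high`, `fixed_low`,
   `fixed_both`, or `neither` — the "duality" of sweep signatures where
   one line fixes an extended haplotype while the other keeps segregating.
4. **Polarization (adjAF).** Within a region, allele frequencies of all
   pools are flipped to 1−AF wherever the lowest-heterozygosity reference
   pool's frequency exceeds 0.5, so the reference haplotype reads ~0 and
   other pools' traces expose the haploblock mosaic; 5-kb window means
   summarize the traces.
5. **Simulation.** A forward Wright–Fisher model of truncation selection
   on standing variation: founder haplotype mosaics from seven partially
   inbred sublines, bidirectional selection on an additive trait, relaxed
   sublines, and pooled-read emission with depth, error and contamination
   noise — with full ground truth (founder paintings, causal loci,
   per-generation frequencies) for pipeline validation.

Input is the PoPoolation2 "sync" format (`chrom  pos  ref` plus one
`A:T:C:G:N:del` column per pool) with a two-column chromosome-length TSV;
outputs are TSV window/region tables, BED6 regions, and JSON summaries.

## Worked example

Simulate a selection experiment with a planted one-line sweep, then run
the pipeline on the high-vs-low generation-55 pair:

```bash
poolsweep simulate --scenarios duality,neutral --seed 1 \
    --out sim.sync --truth truth.json --genome-out genome.tsv
poolsweep run --sync sim.sync --genome genome.tsv \
    --pool-ids HWS55,LWS55,HWS40,LWS40,HWR9,LWR9 \
    --pair HWS55,LWS55 --out-dir out
```

The first command writes 80,000 sites for six pools; the second prints the
run summary:

```json
{
  "n_regions": 2,
  "total_bp": 1616000,
  "genome_bp": 5000000,
  "pct_genome": 32.32,
  "class_counts": {
    "unclassified": 1,
    "fixed_high": 1
  },
  "fst_threshold": 0.9713410686023168
}
```

Reading this: the top 5% of valid 1-kb windows exceeded F_ST ≈ 0.971;
clustering them with a 100-kb merge gap produced two differentiated
regions covering 32% of the (deliberately sweep-dense, 5 Mb) simulated
genome. The one region longer than 0.5 Mb is classed `fixed_high` — the
high line's regional heterozygosity is ≤ 0.1 while the low line still
segregates — which matches the planted scenario: a large-effect allele on
a rare founder haplotype that the high line swept to fixation.
`out/regions.tsv` holds the spans and per-pool heterozygosity summaries,
and `out/adjaf_*.tsv` the polarized allele-frequency matrices in which the
low line's surviving haplotypes appear as alternating shared/divergent
blocks.

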