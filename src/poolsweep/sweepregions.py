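"""Empirical thresholding of window F_ST and calling of differentiated regions.

Windows qualifying above an empirical top-fraction threshold are clustered
into regions when separated by less than a merge gap (100 kb by default);
clusters with fewer than 2 SNPs or shorter than 100 kb are dropped.  Regions
longer than 0.5 Mb are classified by the "duality" of their sweep signature:
whether the high line, the low line, both, or neither is close to fixation
(mean heterozygosity <= 0.1) across the span.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts_io import GenomeTable
from .poolstats import PoolSiteStats

logger = logging.getLogger(__name__)

DEFAULT_TOP_FRACTION = 0.05
DEFAULT_MERGE_GAP = 100_000
DEFAULT_MIN_REGION_SNPS = 2
DEFAULT_MIN_REGION_LEN = 100_000
DEFAULT_HET_CUTOFF = 0.1
DEFAULT_MIN_LEN_FOR_CLASS = 500_000

DUALITY_CLASSES = ("fixed_high", "fixed_low", "fixed_both", "neither")


@dataclass
class DifferentiatedRegion:
    """A merged cluster of supra-threshold F_ST windows.

    Spans are 1-based inclusive; ``length = end - start + 1``.  ``score`` is
    the sum of member-window F_ST values (a strength measure combining
    extent and differentiation, used for ranking regions).
    """

    chrom: str
    start: int
    end: int
    n_windows: int = 0
    mean_fst: float | None = None
    score: float = 0.0
    n_snps: int | None = None
    het_mean: dict = field(default_factory=dict)
    het_median: dict = field(default_factory=dict)
    duality_class: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def empirical_threshold(values, top_fraction: float = DEFAULT_TOP_FRACTION) -> float:
    """Empirical F_ST threshold such that the top ``top_fraction`` of windows
    (by count) lie strictly above it.

    Defined as the smallest observed value with at most
    ``floor(top_fraction * n)`` values strictly above — i.e. the
    ``(n - floor(f n))``-th ascending order statistic.  Boundary ties fall
    below the strict cut, so ties at the threshold never qualify.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no valid window F_ST values to threshold")
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must be in (0, 1)")
    m = math.floor(top_fraction * len(vals))
    return float(np.sort(vals)[len(vals) - m - 1]) if m < len(vals) else float(vals.min())


def qualifying_windows(windows: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Valid windows with F_ST strictly above the threshold, coordinate-sorted."""
    q = windows[(windows["valid"].astype(bool)) & (windows["fst"] > threshold)]
    return q.sort_values(["chrom", "start"]).reset_index(drop=True)


def cluster_windows(qualifying: pd.DataFrame, merge_gap: int = DEFAULT_MERGE_GAP):
    """Merge qualifying windows into regions.

    Two windows join the same cluster iff they sit on the same chromosome
    and the gap between their outer coordinates (next.start - prev.end - 1,
    so overlapping windows have gap <= 0) is smaller than ``merge_gap``.
    Single-pass over coordinate-sorted windows; equivalent to
    transitive-closure merging.
    """
    regions: list[DifferentiatedRegion] = []
    cur = None
    cur_fsts: list[float] = []
    for row in qualifying.itertuples(index=False):
        if cur is not None and row.chrom == cur.chrom and (row.start - cur.end - 1) < merge_gap:
            cur.end = max(cur.end, int(row.end))
            cur.n_windows += 1
            cur_fsts.append(float(row.fst))
        else:
            if cur is not None:
                cur.mean_fst = float(np.mean(cur_fsts))
                cur.score = float(np.sum(cur_fsts))
                regions.append(cur)
            cur = DifferentiatedRegion(row.chrom, int(row.start), int(row.end), n_windows=1)
            cur_fsts = [float(row.fst)]
    if cur is not None:
        cur.mean_fst = float(np.mean(cur_fsts))
        cur.score = float(np.sum(cur_fsts))
        regions.append(cur)
    return regions


def count_region_snps(region: DifferentiatedRegion, stats: PoolSiteStats) -> int:
    mask = stats.region_mask(region.chrom, region.start, region.end)
    return int((stats.is_snp & mask).sum())


def filter_regions(
    regions,
    stats: PoolSiteStats,
    min_region_snps: int = DEFAULT_MIN_REGION_SNPS,
    min_region_len: int = DEFAULT_MIN_REGION_LEN,
):
    """Drop clusters with fewer than ``min_region_snps`` SNPs or shorter than
    ``min_region_len`` bp; annotates the surviving regions' ``n_snps``."""
    kept = []
    for r in regions:
        r.n_snps = count_region_snps(r, stats)
        if r.length >= min_region_len and r.n_snps >= min_region_snps:
            kept.append(r)
    return kept


def region_het_summary(region: DifferentiatedRegion, stats: PoolSiteStats, pool: str):
    """Mean and median site heterozygosity of one pool across the region span.

    Only coverage-passing sites with a defined frequency contribute; returns
    ``(nan, nan)`` if there are none.
    """
    j = stats.pool_index(pool)
    mask = stats.region_mask(region.chrom, region.start, region.end)
    h = stats.het[mask, j]
    ok = stats.coverage_ok[mask, j] & ~np.isnan(h)
    if not ok.any():
        return (float("nan"), float("nan"))
    return (float(np.mean(h[ok])), float(np.median(h[ok])))


def annotate_heterozygosity(regions, stats: PoolSiteStats, pools=None):
    """Fill ``het_mean``/``het_median`` for each region and listed pool."""
    pools = list(pools) if pools is not None else list(stats.pool_ids)
    for r in regions:
        for p in pools:
            r.het_mean[p], r.het_median[p] = region_het_summary(r, stats, p)
    return regions


def classify_duality(
    region: DifferentiatedRegion,
    high_pool: str,
    low_pool: str,
    het_cutoff: float = DEFAULT_HET_CUTOFF,
    min_len_for_class: int = DEFAULT_MIN_LEN_FOR_CLASS,
) -> str:
    """Duality class of a region from per-line mean heterozygosity.

    A line is "fixed" when its regional mean heterozygosity is <= the cutoff
    (0.1 by default, boundary inclusive).  Classification applies only to
    regions longer than ``min_len_for_class``; shorter regions are labeled
    ``unclassified``.
    """
    if region.length <= min_len_for_class:
        region.duality_class = "unclassified"
        return region.duality_class
    hh = region.het_mean.get(high_pool, float("nan"))
    hl = region.het_mean.get(low_pool, float("nan"))
    if np.isnan(hh) or np.isnan(hl):
        logger.warning(
            "region %s:%d-%d lacks heterozygosity for %s/%s; unclassified",
            region.chrom, region.start, region.end, high_pool, low_pool,
        )
        region.duality_class = "unclassified"
        return region.duality_class
    fixed_h = hh <= het_cutoff
    fixed_l = hl <= het_cutoff
    if fixed_h and fixed_l:
        region.duality_class = "fixed_both"
    elif fixed_h:
        region.duality_class = "fixed_high"
    elif fixed_l:
        region.duality_class = "fixed_low"
    else:
        region.duality_class = "neither"
    return region.duality_class


def genome_summary(regions, genome: GenomeTable) -> dict:
    """Totals over called regions: bp covered, % of genome, class counts."""
    total = 0
    class_counts: dict[str, int] = {}
    for r in regions:
        if r.chrom not in genome:
            raise ValueError(f"region chromosome {r.chrom!r} not in genome table")
        total += r.length
        cls = r.duality_class or "unclassified"
        class_counts[cls] = class_counts.get(cls, 0) + 1
    genome_bp = genome.total_bp
    return {
        "n_regions": len(regions),
        "total_bp": int(total),
        "genome_bp": int(genome_bp),
        "pct_genome": 100.0 * total / genome_bp if genome_bp else 0.0,
        "class_counts": class_counts,
    }


def divergent_site_count(
    region: DifferentiatedRegion,
    stats: PoolSiteStats,
    pool_pair: tuple,
    delta: float = 0.9,
):
    """Count sites in the span whose between-pool allele-frequency difference
    exceeds ``delta``.

    Returns ``(n_divergent, n_total)`` where ``n_total`` counts sites
    coverage-passing (with defined frequency) in both pools.
    """
    i1 = stats.pool_index(pool_pair[0])
    i2 = stats.pool_index(pool_pair[1])
    mask = stats.region_mask(region.chrom, region.start, region.end)
    p = stats.freq[mask][:, [i1, i2]]
    ok = stats.coverage_ok[mask][:, [i1, i2]].all(axis=1) & ~np.isnan(p).any(axis=1)
    diffs = np.abs(p[ok, 0] - p[ok, 1])
    return int((diffs > delta).sum()), int(ok.sum())


def call_regions(
    windows: pd.DataFrame,
    stats: PoolSiteStats,
    high_pool: str,
    low_pool: str,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_region_snps: int = DEFAULT_MIN_REGION_SNPS,
    min_region_len: int = DEFAULT_MIN_REGION_LEN,
    het_cutoff: float = DEFAULT_HET_CUTOFF,
    min_len_for_class: int = DEFAULT_MIN_LEN_FOR_CLASS,
    threshold: float | None = None,
):
    """Full region-calling pass: threshold, cluster, filter, annotate, classify.

    Returns ``(regions, threshold)``; regions are coordinate-sorted.
    """
    valid_fst = windows.loc[windows["valid"].astype(bool), "fst"]
    if threshold is None:
        threshold = empirical_threshold(valid_fst, top_fraction)
    q = qualifying_windows(windows, threshold)
    regions = cluster_windows(q, merge_gap)
    regions = filter_regions(regions, stats, min_region_snps, min_region_len)
    annotate_heterozygosity(regions, stats)
    for r in regions:
        classify_duality(r, high_pool, low_pool, het_cutoff, min_len_for_class)
    return regions, float(threshold)


def regions_to_dataframe(regions) -> pd.DataFrame:
    rows = []
    for r in regions:
        row = {
            "chrom": r.chrom, "start": r.start, "end": r.end, "length": r.length,
            "n_windows": r.n_windows, "mean_fst": r.mean_fst, "score": r.score,
            "n_snps": r.n_snps, "duality_class": r.duality_class,
        }
        for p, v in r.het_mean.items():
            row[f"het_mean_{p}"] = v
        for p, v in r.het_median.items():
            row[f"het_median_{p}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
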