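import numpy as np
import pandas as pd
import pytest

from poolsweep import sweepregions
from poolsweep.counts_io import GenomeTable
from poolsweep.poolstats import biallelify
from poolsweep.sweepregions import (
    DifferentiatedRegion,
    classify_duality,
    cluster_windows,
    divergent_site_count,
    empirical_threshold,
    filter_regions,
    genome_summary,
    qualifying_windows,
    region_het_summary,
)

from conftest import two_pool_table


def brute_force_threshold(values, top_fraction):
    """Smallest observed value with at most floor(f*n) values strictly above."""
    vals = sorted(values)
    n = len(vals)
    limit = int(np.floor(top_fraction * n))
    for v in vals:
        if sum(1 for x in vals if x > v) <= limit:
            return v
    return vals[-1]


def windows_frame(spans, chrom="chr1", fst=0.99):
    return pd.DataFrame({
        "chrom": chrom,
        "start": [s for s, _ in spans],
        "end": [e for _, e in spans],
        "fst": fst,
        "n_snps": 5,
        "covered_fraction": 1.0,
        "valid": True,
    })


def brute_force_clusters(spans, merge_gap):
    """Transitive-closure merging over all pairs (independent oracle)."""
    spans = sorted(spans)
    parent = list(range(len(spans)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            lo = max(spans[i][0], spans[j][0])
            hi = min(spans[i][1], spans[j][1])
            gap = lo - hi - 1  # negative when overlapping
            if gap < merge_gap:
                parent[find(j)] = find(i)
    groups = {}
    for i, s in enumerate(spans):
        groups.setdefault(find(i), []).append(s)
    return sorted((min(a for a, _ in g), max(b for _, b in g)) for g in groups.values())


class TestEmpiricalThreshold:
    def test_uniform_integers_top_five_percent(self):
        vals = list(range(1, 101))
        expected = brute_force_threshold(vals, 0.05)
        thr = empirical_threshold(vals, 0.05)
        assert thr == expected
        assert sum(v > thr for v in vals) == 5

    def test_all_equal_selects_none_strictly_above(self):
        thr = empirical_threshold([0.7] * 40, 0.05)
        assert thr == 0.7
        assert sum(v > thr for v in [0.7] * 40) == 0

    def test_single_outlier_in_twenty(self):
        vals = [0.1] * 19 + [5.0]
        thr = empirical_threshold(vals, 0.05)
        assert thr == brute_force_threshold(vals, 0.05)
        assert [v for v in vals if v > thr] == [5.0]

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(25):
            vals = rng.normal(size=rng.integers(5, 400)).tolist()
            f = float(rng.uniform(0.01, 0.4))
            assert empirical_threshold(vals, f) == brute_force_threshold(vals, f)

    def test_nan_ignored_and_empty_rejected(self):
        assert empirical_threshold([np.nan, 1.0, 2.0], 0.5) == 1.0
        with pytest.raises(ValueError):
            empirical_threshold([np.nan], 0.05)


class TestClusterWindows:
    def test_gap_under_100kb_merges(self):
        w = windows_frame([(1, 1000), (90_001, 91_000)])
        regions = cluster_windows(w, merge_gap=100_000)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1, 91_000)

    def test_gap_over_100kb_splits(self):
        w = windows_frame([(1, 1000), (150_001, 151_000)])
        regions = cluster_windows(w, merge_gap=100_000)
        assert len(regions) == 2

    def test_boundary_gap_exactly_100kb_splits(self):
        # gap = next.start - prev.end - 1 = 100_000 exactly -> not < merge_gap
        w = windows_frame([(1, 1000), (101_001, 102_000)])
        assert len(cluster_windows(w, merge_gap=100_000)) == 2

    def test_overlapping_windows_union(self):
        w = windows_frame([(1, 1000), (501, 1500), (1001, 2000)])
        regions = cluster_windows(w, merge_gap=100_000)
        assert len(regions) == 1
        assert regions[0].n_windows == 3
        assert (regions[0].start, regions[0].end) == (1, 2000)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_transitive_closure_on_random_sets(self, rng, trial):
        n = int(rng.integers(5, 200))
        starts = np.sort(rng.choice(np.arange(1, 2_000_000, 500), size=n, replace=False))
        spans = [(int(s), int(s) + 999) for s in starts]
        gap = int(rng.choice([10_000, 50_000, 100_000]))
        got = [(r.start, r.end) for r in cluster_windows(windows_frame(spans), merge_gap=gap)]
        assert got == brute_force_clusters(spans, gap)

    def test_idempotent_region_spans(self, rng):
        starts = np.sort(rng.choice(np.arange(1, 500_000, 500), size=50, replace=False))
        spans = [(int(s), int(s) + 999) for s in starts]
        once = cluster_windows(windows_frame(spans), merge_gap=30_000)
        again = cluster_windows(windows_frame([(r.start, r.end) for r in once]), merge_gap=30_000)
        assert [(r.start, r.end) for r in once] == [(r.start, r.end) for r in again]


def snp_table(positions, chrom="chr1"):
    rows = [(p, "A", {"A": 15, "T": 15}, {"A": 30}) for p in positions]
    return biallelify(two_pool_table(rows, chrom=chrom))


class TestFilterRegions:
    def test_short_region_removed(self):
        stats = snp_table(range(1000, 51_000, 1000))
        regions = [DifferentiatedRegion("chr1", 1, 91_000)]
        assert filter_regions(regions, stats) == []

    def test_single_snp_region_removed(self):
        stats = snp_table([5000])
        regions = [DifferentiatedRegion("chr1", 1, 120_000)]
        assert filter_regions(regions, stats) == []

    def test_two_snp_region_kept(self):
        stats = snp_table([5000, 6000])
        regions = [DifferentiatedRegion("chr1", 1, 120_000)]
        kept = filter_regions(regions, stats)
        assert len(kept) == 1 and kept[0].n_snps == 2

    def test_boundary_length_kept(self):
        stats = snp_table([5000, 6000])
        regions = [DifferentiatedRegion("chr1", 1, 100_000)]
        assert len(filter_regions(regions, stats)) == 1


class TestRegionHetSummary:
    def test_fixed_line_gives_zero(self):
        rows = [(p, "A", {"A": 30}, {"T": 30}) for p in (100, 200, 300)]
        stats = biallelify(two_pool_table(rows))
        region = DifferentiatedRegion("chr1", 1, 1000)
        assert region_het_summary(region, stats, "P1") == (0.0, 0.0)

    def test_hand_worked_mean_and_median(self):
        # het values 0.5, 0.375, 0 in pool 1
        rows = [
            (100, "A", {"A": 15, "T": 15}, {"A": 30}),
            (200, "A", {"A": 30, "T": 10}, {"A": 40}),
            (300, "A", {"A": 30}, {"T": 30}),
        ]
        stats = biallelify(two_pool_table(rows))
        region = DifferentiatedRegion("chr1", 1, 1000)
        mean_h, median_h = region_het_summary(region, stats, "P1")
        assert mean_h == pytest.approx((0.5 + 0.375 + 0.0) / 3)
        assert median_h == pytest.approx(0.375)

    def test_no_usable_sites_gives_nan(self):
        rows = [(100, "A", {"A": 5}, {"T": 30})]  # pool1 below min coverage
        stats = biallelify(two_pool_table(rows))
        region = DifferentiatedRegion("chr1", 1, 1000)
        mean_h, median_h = region_het_summary(region, stats, "P1")
        assert np.isnan(mean_h) and np.isnan(median_h)


class TestClassifyDuality:
    def _region(self, hh, hl, length=600_000):
        r = DifferentiatedRegion("chr1", 1, length)
        r.het_mean = {"H": hh, "L": hl}
        return r

    @pytest.mark.parametrize("hh,hl,expected", [
        (0.05, 0.30, "fixed_high"),
        (0.30, 0.05, "fixed_low"),
        (0.08, 0.09, "fixed_both"),
        (0.10, 0.10, "fixed_both"),   # boundary: <= 0.1 counts as fixed
        (0.25, 0.30, "neither"),
        (0.10, 0.11, "fixed_high"),
    ])
    def test_classes(self, hh, hl, expected):
        assert classify_duality(self._region(hh, hl), "H", "L") == expected

    def test_short_regions_unclassified(self):
        r = self._region(0.05, 0.30, length=400_000)
        assert classify_duality(r, "H", "L") == "unclassified"
        # boundary: exactly 0.5 Mb is not classified (rule is strictly greater)
        r2 = self._region(0.05, 0.30, length=500_000)
        assert classify_duality(r2, "H", "L") == "unclassified"

    def test_missing_het_unclassified(self):
        r = self._region(float("nan"), 0.3)
        assert classify_duality(r, "H", "L") == "unclassified"

    def test_partition_property(self, rng):
        regions = [self._region(rng.uniform(0, 0.4), rng.uniform(0, 0.4),
                                length=int(rng.choice([300_000, 700_000])))
                   for _ in range(200)]
        for r in regions:
            classify_duality(r, "H", "L")
        long_regions = [r for r in regions if r.length > 500_000]
        counts = {}
        for r in long_regions:
            counts[r.duality_class] = counts.get(r.duality_class, 0) + 1
        assert sum(counts.get(c, 0) for c in sweepregions.DUALITY_CLASSES) == len(long_regions)


class TestGenomeSummary:
    def test_single_region_fraction(self):
        g = GenomeTable.from_pairs([("chr1", 10_000_000)])
        r = DifferentiatedRegion("chr1", 1_000_001, 2_000_000)
        s = genome_summary([r], g)
        assert s["total_bp"] == 1_000_000
        assert s["pct_genome"] == pytest.approx(10.0)

    def test_zero_regions(self):
        g = GenomeTable.from_pairs([("chr1", 1000)])
        s = genome_summary([], g)
        assert s["total_bp"] == 0 and s["pct_genome"] == 0.0

    def test_matches_brute_force_and_weighting(self, rng):
        g = GenomeTable.from_pairs([("chr1", 5_000_000), ("chr2", 3_000_000)])
        regions = []
        for chrom, L in [("chr1", 5_000_000), ("chr2", 3_000_000)]:
            for _ in range(5):
                start = int(rng.integers(1, L - 200_000))
                regions.append(DifferentiatedRegion(chrom, start, start + int(rng.integers(1000, 150_000))))
        s = genome_summary(regions, g)
        expected = sum(r.length for r in regions)
        assert s["total_bp"] == expected
        assert s["pct_genome"] == pytest.approx(100 * expected / 8_000_000)
        assert 0 <= s["pct_genome"] <= 100

    def test_unknown_chrom_rejected(self):
        g = GenomeTable.from_pairs([("chr1", 1000)])
        with pytest.raises(ValueError):
            genome_summary([DifferentiatedRegion("chrZ", 1, 10)], g)


class TestDivergentSiteCount:
    def test_oppositely_fixed_sites(self):
        rows = [(100 * (i + 1), "A", {"A": 30}, {"T": 30}) for i in range(100)]
        stats = biallelify(two_pool_table(rows))
        region = DifferentiatedRegion("chr1", 1, 100_000)
        assert divergent_site_count(region, stats, ("P1", "P2")) == (100, 100)

    def test_identical_pools(self):
        rows = [(100 * (i + 1), "A", {"A": 15, "T": 15}, {"A": 15, "T": 15}) for i in range(20)]
        stats = biallelify(two_pool_table(rows))
        region = DifferentiatedRegion("chr1", 1, 100_000)
        assert divergent_site_count(region, stats, ("P1", "P2")) == (0, 20)

    def test_matches_brute_force(self, rng):
        rows = []
        for i in range(200):
            a1 = int(rng.integers(0, 31))
            a2 = int(rng.integers(0, 31))
            rows.append((100 * (i + 1), "A", {"A": a1, "T": 30 - a1}, {"A": a2, "T": 30 - a2}))
        stats = biallelify(two_pool_table(rows))
        region = DifferentiatedRegion("chr1", 1, 100_000)
        n_div, n_tot = divergent_site_count(region, stats, ("P1", "P2"), delta=0.9)
        freq = stats.freq
        expected = sum(1 for i in range(stats.n_sites) if abs(freq[i, 0] - freq[i, 1]) > 0.9)
        assert n_div == expected
        assert n_tot == stats.n_sites


class TestThresholdMonotonicity:
    def test_total_region_bp_never_grows_with_threshold(self, rng):
        starts = np.sort(rng.choice(np.arange(1, 3_000_000, 500), size=400, replace=False))
        w = pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": starts + 999,
            "fst": rng.uniform(0, 1, size=400), "n_snps": 5,
            "covered_fraction": 1.0, "valid": True,
        })
        totals = []
        for thr in [0.0, 0.25, 0.5, 0.75, 0.95]:
            regions = cluster_windows(qualifying_windows(w, thr))
            totals.append(sum(r.length for r in regions))
        assert totals == sorted(totals, reverse=True)
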