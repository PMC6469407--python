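"""Per-site pool statistics and windowed pairwise F_ST.

Sites are reduced to the two most frequent nucleotides pooled across all
populations (``biallelify``); per-pool allele frequencies are read
frequencies of the table-wide minor allele, and heterozygosity is the
expected heterozygosity ``2 p (1 - p)`` of that frequency (no finite-pool
correction, so H ranges over [0, 0.5]).

Between-pool differentiation uses the per-site two-pool estimator of
Karlsson et al.: with minor-allele count ``a`` of read depth ``n`` in each
pool and ``h_i = a_i (n_i - a_i) / (n_i (n_i - 1))``,

    N = (a1/n1 - a2/n2)^2 - h1/n1 - h2/n2
    D = N + h1 + h2

and a window's F_ST is the ratio of sums ΣN / ΣD over the SNPs it contains.
Windows are laid on a fixed grid (anchored at position 1, stride = half the
window size, i.e. 50% overlap); the defaults reproduce the standard pool-seq
filter set: minimum pooled minor count 3, per-pool depth within [10, 100],
and minimum coverage fraction 1.  Negative window F_ST values are reported
as computed — clamping would bias downstream empirical quantiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts_io import BASE_ORDER, SiteCountTable

logger = logging.getLogger(__name__)

# sync class order is A,T,C,G; alphabetical order breaks frequency ties
_ALPHA = ("A", "C", "G", "T")
_SYNC_TO_ALPHA = [BASE_ORDER.index(b) for b in _ALPHA]  # A,C,G,T columns in sync order

DEFAULT_MIN_COUNT = 3
DEFAULT_MIN_COV = 10
DEFAULT_MAX_COV = 100
DEFAULT_WINDOW = 1000
DEFAULT_MIN_FRACTION = 1.0


@dataclass
class PoolSiteStats:
    """Biallelified site table: counts, frequencies and flags for every pool.

    ``a`` and ``n`` are the minor-allele count and the biallelic depth
    (major + minor reads; N and deletion reads never enter frequency math).
    ``freq`` is ``a / n`` (NaN where ``n == 0``), ``het`` is ``2 p (1-p)``.
    The minor-allele identity is shared across pools at each site.
    """

    chrom: np.ndarray
    pos: np.ndarray
    major: np.ndarray  # base chars
    minor: np.ndarray
    a: np.ndarray      # (n_sites, n_pools) minor-allele read counts
    n: np.ndarray      # (n_sites, n_pools) major+minor read counts
    depth: np.ndarray  # (n_sites, n_pools) total depth incl. N/del
    is_snp: np.ndarray           # (n_sites,) pooled minor count >= min_count
    coverage_ok: np.ndarray      # (n_sites, n_pools) depth within [min_cov, max_cov]
    pool_ids: list = field(default_factory=list)
    min_count: int = DEFAULT_MIN_COUNT
    min_cov: int = DEFAULT_MIN_COV
    max_cov: int = DEFAULT_MAX_COV

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def freq(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.n > 0, self.a / np.maximum(self.n, 1), np.nan)

    @property
    def het(self) -> np.ndarray:
        p = self.freq
        return 2.0 * p * (1.0 - p)

    def pool_index(self, pool: str) -> int:
        try:
            return self.pool_ids.index(pool)
        except ValueError:
            raise KeyError(f"unknown pool {pool!r}; have {self.pool_ids}") from None

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        return (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)


def biallelify(
    table: SiteCountTable,
    min_count: int = DEFAULT_MIN_COUNT,
    min_cov: int = DEFAULT_MIN_COV,
    max_cov: int = DEFAULT_MAX_COV,
) -> PoolSiteStats:
    """Reduce raw counts to a shared major/minor allele pair per site.

    The two most frequent nucleotides by counts summed over all pools become
    the major and minor allele; frequency ties are broken by alphabetical
    base order (A < C < G < T).  Other nucleotides and the deletion class are
    dropped from ``a`` and ``n``.  Sites with zero depth in every pool are
    skipped with a log notice.
    """
    acgt = table.counts[:, :, _SYNC_TO_ALPHA]          # (sites, pools, 4) alphabetical
    totals = acgt.sum(axis=1)                           # (sites, 4)
    keep = totals.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("skipping %d all-pool zero-depth sites", n_dropped)
    acgt = acgt[keep]
    totals = totals[keep]

    # stable argsort on negated counts prefers the alphabetically earlier base on ties
    order = np.argsort(-totals, axis=1, kind="stable")
    major_idx = order[:, 0]
    minor_idx = order[:, 1]
    rows = np.arange(len(totals))
    major_counts = acgt[rows, :, major_idx]             # (sites, pools)
    minor_counts = acgt[rows, :, minor_idx]

    alpha = np.array(_ALPHA, dtype=object)
    return PoolSiteStats(
        chrom=table.chrom[keep],
        pos=table.pos[keep],
        major=alpha[major_idx],
        minor=alpha[minor_idx],
        a=minor_counts,
        n=major_counts + minor_counts,
        depth=table.depths()[keep],
        is_snp=minor_counts.sum(axis=1) >= min_count,
        coverage_ok=(table.depths()[keep] >= min_cov) & (table.depths()[keep] <= max_cov),
        pool_ids=table.pool_ids,
        min_count=min_count,
        min_cov=min_cov,
        max_cov=max_cov,
    )


def site_heterozygosity(p: np.ndarray | float) -> np.ndarray | float:
    """Expected heterozygosity 2 p (1 - p) of an allele frequency."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def karlsson_components(a1, n1, a2, n2):
    """Per-site numerator/denominator components of the two-pool F_ST estimator.

    Accepts scalars or arrays; requires depth >= 2 in both pools.
    Returns ``(N, D)`` with ``D = N + h1 + h2``.
    """
    a1 = np.asarray(a1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("karlsson_components requires read depth >= 2 in both pools")
    h1 = a1 * (n1 - a1) / (n1 * (n1 - 1))
    h2 = a2 * (n2 - a2) / (n2 * (n2 - 1))
    num = (a1 / n1 - a2 / n2) ** 2 - h1 / n1 - h2 / n2
    den = num + h1 + h2
    if num.ndim == 0:
        return float(num), float(den)
    return num, den


def _window_grid(chrom_len: int, window_size: int, stride: int) -> np.ndarray:
    """1-based start positions of full windows tiling [1, chrom_len]."""
    if chrom_len < window_size:
        return np.array([], dtype=np.int64)
    return np.arange(1, chrom_len - window_size + 2, stride, dtype=np.int64)


def _site_window_span(pos: np.ndarray, window_size: int, stride: int, n_windows: int):
    """Index range [lo, hi] of grid windows containing each 1-based position."""
    hi = np.minimum((pos - 1) // stride, n_windows - 1)
    lo = np.maximum(-((window_size - pos) // stride), 0)  # ceil((pos - ws)/stride)
    return lo, hi


def window_fst(
    stats: PoolSiteStats,
    pool_pair: tuple,
    chrom_lengths: dict,
    window_size: int = DEFAULT_WINDOW,
    stride: int | None = None,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    coverage_mode: str = "sites",
) -> pd.DataFrame:
    """Sliding-window F_ST between two pools, plus per-pool mean heterozygosity.

    Windows form a fixed half-overlapping grid per chromosome (starts 1,
    1+stride, ...).  A site contributes to a window's F_ST only if it is a
    SNP and both compared pools have depth within the coverage band; a
    window is ``valid`` only if its covered fraction reaches ``min_fraction``
    and the summed denominator is positive.  Invalid windows carry NaN F_ST,
    never 0.

    ``coverage_mode`` sets the covered-fraction denominator: ``"sites"``
    (default) uses only positions present in the count table — appropriate
    for sparse, sites-only tables; ``"positions"`` divides by the full
    window size, matching dense all-sites tables.

    Returns a DataFrame with columns ``chrom, start, end, fst, n_snps,
    covered_fraction, valid`` and one ``het_<pool>`` column per pool.
    """
    if stride is None:
        stride = window_size // 2
    if coverage_mode not in ("sites", "positions"):
        raise ValueError("coverage_mode must be 'sites' or 'positions'")
    i1 = stats.pool_index(pool_pair[0])
    i2 = stats.pool_index(pool_pair[1])

    freq = stats.freq
    het = stats.het
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = _window_grid(int(length), window_size, stride)
        nw = len(starts)
        if nw == 0:
            continue
        cmask = stats.chrom == chrom
        pos = stats.pos[cmask]

        pair_cov = stats.coverage_ok[cmask][:, [i1, i2]].all(axis=1)
        pair_n_ok = (stats.n[cmask][:, [i1, i2]] >= 2).all(axis=1)
        usable = pair_cov & pair_n_ok
        snp = stats.is_snp[cmask] & usable

        num = np.zeros(len(pos))
        den = np.zeros(len(pos))
        if snp.any():
            n_, d_ = karlsson_components(
                stats.a[cmask][snp, i1], stats.n[cmask][snp, i1],
                stats.a[cmask][snp, i2], stats.n[cmask][snp, i2],
            )
            num[snp] = np.atleast_1d(n_)
            den[snp] = np.atleast_1d(d_)

        sum_num = np.zeros(nw)
        sum_den = np.zeros(nw)
        n_snps = np.zeros(nw, dtype=np.int64)
        n_present = np.zeros(nw, dtype=np.int64)
        n_pass = np.zeros(nw, dtype=np.int64)
        het_sums = np.zeros((nw, stats.depth.shape[1]))
        het_ns = np.zeros((nw, stats.depth.shape[1]), dtype=np.int64)

        if len(pos):
            lo, hi = _site_window_span(pos, window_size, stride, nw)
            pool_cov = stats.coverage_ok[cmask]
            pool_het = np.where(pool_cov & ~np.isnan(het[cmask]), het[cmask], 0.0)
            pool_het_n = (pool_cov & ~np.isnan(het[cmask])).astype(np.int64)
            max_span = int((hi - lo).max()) + 1
            for off in range(max_span):
                w = lo + off
                sel = w <= hi
                idx = w[sel]
                np.add.at(sum_num, idx, num[sel])
                np.add.at(sum_den, idx, den[sel])
                np.add.at(n_snps, idx, snp[sel].astype(np.int64))
                np.add.at(n_present, idx, 1)
                np.add.at(n_pass, idx, usable[sel].astype(np.int64))
                np.add.at(het_sums, idx, pool_het[sel])
                np.add.at(het_ns, idx, pool_het_n[sel])

        if coverage_mode == "sites":
            with np.errstate(invalid="ignore"):
                covered = np.where(n_present > 0, n_pass / np.maximum(n_present, 1), 0.0)
        else:
            covered = n_pass / float(window_size)

        valid = (covered >= min_fraction) & (sum_den > 0) & (n_snps >= 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where(valid, sum_num / np.where(sum_den > 0, sum_den, np.nan), np.nan)

        df = pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + window_size - 1,
            "fst": fst,
            "n_snps": n_snps,
            "covered_fraction": covered,
            "valid": valid,
        })
        with np.errstate(invalid="ignore"):
            mean_het = np.where(het_ns > 0, het_sums / np.maximum(het_ns, 1), np.nan)
        for j, pid in enumerate(stats.pool_ids):
            df[f"het_{pid}"] = mean_het[:, j]
        frames.append(df)

    if not frames:
        cols = ["chrom", "start", "end", "fst", "n_snps", "covered_fraction", "valid"]
        cols += [f"het_{p}" for p in stats.pool_ids]
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def window_heterozygosity(
    stats: PoolSiteStats,
    chrom_lengths: dict,
    window_size: int = DEFAULT_WINDOW,
    stride: int | None = None,
) -> pd.DataFrame:
    """Per-pool mean site heterozygosity on the same fixed window grid.

    Means are taken over coverage-passing sites only; windows with none get
    NaN.  Returns ``chrom, start, end`` plus one ``het_<pool>`` column.
    """
    if stride is None:
        stride = window_size // 2
    het = stats.het
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = _window_grid(int(length), window_size, stride)
        nw = len(starts)
        if nw == 0:
            continue
        cmask = stats.chrom == chrom
        pos = stats.pos[cmask]
        sums = np.zeros((nw, len(stats.pool_ids)))
        ns = np.zeros((nw, len(stats.pool_ids)), dtype=np.int64)
        if len(pos):
            lo, hi = _site_window_span(pos, window_size, stride, nw)
            ok = stats.coverage_ok[cmask] & ~np.isnan(het[cmask])
            vals = np.where(ok, het[cmask], 0.0)
            for off in range(int((hi - lo).max()) + 1):
                w = lo + off
                sel = w <= hi
                idx = w[sel]
                np.add.at(sums, idx, vals[sel])
                np.add.at(ns, idx, ok[sel].astype(np.int64))
        with np.errstate(invalid="ignore"):
            mean_het = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
        df = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + window_size - 1})
        for j, pid in enumerate(stats.pool_ids):
            df[f"het_{pid}"] = mean_het[:, j]
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"] + [f"het_{p}" for p in stats.pool_ids])
    return pd.concat(frames, ignore_index=True)
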