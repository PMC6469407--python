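"""Adjusted allele frequencies (adjAF) and haploblock-mosaic summaries.

Within a region of interest, allele frequencies of all pools are polarized
against the pool of lowest haplotypic complexity — operationalized as the
pool with minimum regional mean heterozygosity, which in practice carries
one fixed extended haplotype with raw frequencies near 0 or 1.  At every
site where that reference pool's frequency exceeds 0.5, the frequencies of
ALL pools are flipped to ``1 - AF``; the reference trace then reads ~0 along
its fixed haplotype, and another pool's adjAF measures its allele-sharing
distance from that haplotype.  Flips are applied identically across pools,
so between-pool divergence ``|p_i - p_j|`` is invariant under polarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .poolstats import PoolSiteStats

DEFAULT_ADJAF_WINDOW = 5000


@dataclass
class PolarizedMatrix:
    """Per-site adjusted allele frequencies for one region.

    ``adjaf`` has shape (n_sites, n_pools); ``flipped`` marks sites where
    the 1-AF flip was applied, ``ref_undefined`` marks sites left unflipped
    because the reference pool had no defined frequency there.
    """

    chrom: str
    start: int
    end: int
    pos: np.ndarray
    pool_ids: list
    reference_pool: str
    adjaf: np.ndarray
    flipped: np.ndarray
    ref_undefined: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos})
        for j, p in enumerate(self.pool_ids):
            df[f"adjaf_{p}"] = self.adjaf[:, j]
        df["flipped"] = self.flipped
        df["ref_undefined"] = self.ref_undefined
        return df


def choose_reference_pool(stats: PoolSiteStats, chrom: str, start: int, end: int,
                          pools=None) -> str:
    """Pool with the lowest regional mean heterozygosity (lowest haplotypic
    complexity); ties broken by declared pool order."""
    pools = list(pools) if pools is not None else list(stats.pool_ids)
    mask = stats.region_mask(chrom, start, end)
    if not mask.any():
        raise ValueError(f"no sites in {chrom}:{start}-{end}")
    het = stats.het[mask]
    cov = stats.coverage_ok[mask]
    best, best_h = None, np.inf
    for p in pools:
        j = stats.pool_index(p)
        ok = cov[:, j] & ~np.isnan(het[:, j])
        if not ok.any():
            continue
        h = float(np.mean(het[ok, j]))
        if h < best_h:  # strict: first pool in declared order wins ties
            best, best_h = p, h
    if best is None:
        raise ValueError(f"no pool has usable data in {chrom}:{start}-{end}")
    return best


def polarize_region(stats: PoolSiteStats, chrom: str, start: int, end: int,
                    reference_pool: str) -> PolarizedMatrix:
    """Build the adjAF matrix for a region.

    Sites where the reference pool's frequency is strictly > 0.5 are flipped
    to ``1 - AF`` in every pool; sites at exactly 0.5 stay unflipped.  Sites
    where the reference frequency is undefined are left unflipped and
    flagged.  Applying the transform twice yields the same matrix
    (idempotence): after a flip the reference frequency is < 0.5.
    """
    jref = stats.pool_index(reference_pool)
    mask = stats.region_mask(chrom, start, end)
    pos = stats.pos[mask]
    p = stats.freq[mask].copy()
    pref = p[:, jref]
    undefined = np.isnan(pref)
    flip = ~undefined & (pref > 0.5)
    p[flip] = 1.0 - p[flip]
    return PolarizedMatrix(
        chrom=chrom, start=start, end=end, pos=pos,
        pool_ids=list(stats.pool_ids), reference_pool=reference_pool,
        adjaf=p, flipped=flip, ref_undefined=undefined,
    )


def window_adjaf(matrix: PolarizedMatrix, window_size: int = DEFAULT_ADJAF_WINDOW) -> pd.DataFrame:
    """Mean adjAF per pool over a non-overlapping window grid.

    The grid is anchored at the region start; windows with no sites (or no
    defined frequencies for a pool) carry NaN.  Returns ``start, end`` plus
    one ``adjaf_<pool>`` column per pool.
    """
    n_windows = max(1, -(-(matrix.end - matrix.start + 1) // window_size))
    starts = matrix.start + window_size * np.arange(n_windows, dtype=np.int64)
    ends = np.minimum(starts + window_size - 1, matrix.end)
    out = pd.DataFrame({"start": starts, "end": ends})
    if matrix.n_sites:
        widx = (matrix.pos - matrix.start) // window_size
    else:
        widx = np.array([], dtype=np.int64)
    for j, p in enumerate(matrix.pool_ids):
        vals = matrix.adjaf[:, j]
        ok = ~np.isnan(vals)
        sums = np.bincount(widx[ok], weights=vals[ok], minlength=n_windows)
        ns = np.bincount(widx[ok], minlength=n_windows)
        with np.errstate(invalid="ignore"):
            out[f"adjaf_{p}"] = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return out


def segment_haploblocks(window_means: pd.DataFrame, pool: str,
                        low: float = 0.1, high: float = 0.4, min_run: int = 3):
    """Heuristic haploblock caller on a pool's windowed adjAF trace.

    Maximal runs of at least ``min_run`` consecutive windows that are all
    <= ``low`` become ``"shared"`` blocks (allele content matching the
    reference haplotype); runs all >= ``high`` become ``"divergent"``
    blocks.  NaN windows and intermediate values break runs and stay
    unassigned.  This is presentation-layer heuristics, not an inference
    method, and is off by default in the pipeline.

    Returns a list of ``(start, end, label)`` genomic spans.
    """
    vals = window_means[f"adjaf_{pool}"].to_numpy(dtype=float)
    state = np.full(len(vals), 0, dtype=np.int8)  # 0 unassigned, 1 shared, 2 divergent
    with np.errstate(invalid="ignore"):
        state[~np.isnan(vals) & (vals <= low)] = 1
        state[~np.isnan(vals) & (vals >= high)] = 2
    blocks = []
    i = 0
    while i < len(state):
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(state) and state[j + 1] == state[i]:
            j += 1
        if j - i + 1 >= min_run:
            blocks.append((
                int(window_means["start"].iloc[i]),
                int(window_means["end"].iloc[j]),
                "shared" if state[i] == 1 else "divergent",
            ))
        i = j + 1
    return blocks
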