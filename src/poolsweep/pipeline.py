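"""End-to-end orchestration: counts -> windows -> regions -> polarization.

A :class:`RunConfig` carries every stage parameter; the defaults are the
standard analysis values (1 kb windows with 50% overlap, pooled minor count
>= 3, per-pool depth within [10, 100], coverage fraction 1, top-5%
empirical threshold, 100 kb merge gap, >= 2 SNPs and >= 100 kb per region,
fixation cutoff H <= 0.1 for regions > 0.5 Mb, 5 kb adjAF windows).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import counts_io, poolstats, polarize as polarize_mod, sweepregions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sync_path: str = ""
    genome_path: str = ""
    pool_ids: list = field(default_factory=list)
    high_pool: str = ""
    low_pool: str = ""
    out_dir: str = "poolsweep_out"
    # window stage
    window_size: int = 1000
    stride: int | None = None          # defaults to window_size // 2 (50% overlap)
    min_count: int = 3
    min_cov: int = 10
    max_cov: int = 100
    min_fraction: float = 1.0
    coverage_mode: str = "sites"
    # region stage
    top_fraction: float = 0.05
    merge_gap: int = 100_000
    min_region_snps: int = 2
    min_region_len: int = 100_000
    het_cutoff: float = 0.1
    min_len_for_class: int = 500_000
    # polarization stage
    adjaf_window: int = 5000
    polarize_regions: str = "all"      # "all", "none", or "chrN:start-end" spec
    reference_pool: str = "auto"
    seed: int = 0

    def param_hash(self) -> str:
        """Hash of the analysis parameters (paths and output locations excluded)."""
        d = {k: v for k, v in asdict(self).items()
             if k not in ("sync_path", "genome_path", "out_dir")}
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    windows: object
    regions: list
    threshold: float
    summary: dict
    polarized: dict


def run_pipeline(config: RunConfig, table=None, genome=None) -> RunResult:
    """Execute windows -> regions -> polarization and write all outputs.

    ``table``/``genome`` may be passed in memory (e.g. straight from the
    simulator); otherwise they are read from the configured paths.  Empty
    inputs produce empty outputs and a warning, not an error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run parameters %s (hash %s)", asdict(config), config.param_hash())

    if table is None:
        table = counts_io.read_sync(config.sync_path, config.pool_ids)
    if genome is None:
        genome = counts_io.read_genome_table(config.genome_path)
    high, low = config.high_pool, config.low_pool
    if not high or not low:
        raise ValueError("high_pool and low_pool must be set")

    stats = poolstats.biallelify(table, config.min_count, config.min_cov, config.max_cov)
    windows = poolstats.window_fst(
        stats, (high, low), genome.lengths,
        window_size=config.window_size, stride=config.stride,
        min_fraction=config.min_fraction, coverage_mode=config.coverage_mode,
    )
    counts_io.write_windows_tsv(windows, out / "windows.tsv")

    if len(windows) == 0 or not windows["valid"].any():
        logger.warning("no valid windows; writing empty region outputs")
        regions, threshold = [], float("nan")
    else:
        regions, threshold = sweepregions.call_regions(
            windows, stats, high, low,
            top_fraction=config.top_fraction, merge_gap=config.merge_gap,
            min_region_snps=config.min_region_snps, min_region_len=config.min_region_len,
            het_cutoff=config.het_cutoff, min_len_for_class=config.min_len_for_class,
        )
    counts_io.write_regions_bed(regions, out / "regions.bed", genome)
    sweepregions.regions_to_dataframe(regions).to_csv(out / "regions.tsv", sep="\t", index=False)

    summary = sweepregions.genome_summary(regions, genome)
    summary["fst_threshold"] = threshold
    summary["param_hash"] = config.param_hash()
    with open(out / "summary.json", "wt") as fh:
        json.dump(summary, fh, indent=2, default=float)

    polarized = {}
    if config.polarize_regions != "none":
        if config.polarize_regions == "all":
            targets = [(r.chrom, r.start, r.end) for r in regions]
        else:
            chrom, span = config.polarize_regions.split(":")
            a, b = span.split("-")
            targets = [(chrom, int(a), int(b))]
        for chrom, start, end in targets:
            try:
                ref = (
                    polarize_mod.choose_reference_pool(stats, chrom, start, end)
                    if config.reference_pool == "auto" else config.reference_pool
                )
                matrix = polarize_mod.polarize_region(stats, chrom, start, end, ref)
            except ValueError as exc:
                logger.warning("skipping polarization of %s:%d-%d: %s", chrom, start, end, exc)
                continue
            means = polarize_mod.window_adjaf(matrix, config.adjaf_window)
            tag = f"{chrom}_{start}_{end}"
            matrix.to_dataframe().to_csv(out / f"adjaf_{tag}.tsv", sep="\t", index=False)
            means.to_csv(out / f"adjaf_windows_{tag}.tsv", sep="\t", index=False)
            polarized[(chrom, start, end)] = (matrix, means)

    return RunResult(windows, regions, threshold, summary, polarized)
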