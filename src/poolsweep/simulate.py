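"""Forward simulator of bidirectional truncation selection on standing variation.

The generative model mirrors the demography of a divergent selection
experiment founded by crossing a small number of partially inbred sublines:

* a handful of deep ancestral haplotypes recombine (a configurable number of
  historical crossovers) into subline haplotype mosaics, whose ancestral
  "painting" is recorded as ground truth;
* a founder population of balanced subline crosses seeds two closed lines,
  selected upward ("high") and downward ("low") by truncation on an additive
  polygenic trait with configurable heritability;
* relaxed sublines branch off at a configurable generation and drift without
  selection;
* at snapshot generations, pooled sequencing is emulated: a finite pool of
  individuals is sampled, read depth is drawn per site within a coverage
  band, and reads are drawn binomially with a per-base sequencing error.

Two mating systems are available.  ``wright_fisher``: each gamete comes from
a uniformly, independently chosen parent (among the selected ones), so drift
is exactly binomial — E[ΔAF] = 0, Var(ΔAF) = p(1-p)/2N, and expected
heterozygosity decays as H0 (1 - 1/2N)^t without selection; this is the
calibration mode.  ``equalized`` (default): parents contribute as equally as
possible to the gamete pool, emulating a pedigreed breeding scheme
structured to minimize inbreeding and the stochastic fixation of alleles —
diversity then decays more slowly than iid Wright-Fisher at the same census.
A "balanced" transmission mode additionally makes every parent contribute
exactly two complementary gametes, conserving allele frequencies exactly
(the no-drift limit).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .counts_io import BASE_ORDER, SiteCountTable

_BASES = np.array(["A", "C", "G", "T"], dtype=object)
_SYNC_COL = {"A": 0, "T": 1, "C": 2, "G": 3}


@dataclass
class PoolSpec:
    """One sequenced pool: which line, which snapshot, how many individuals."""
    line: str        # "high" | "low"
    stage: str       # "g40" | "g55" | "relaxed"
    size: int = 30


def default_pools() -> dict:
    """The six-pool design: two selected lines at two generations plus the
    two relaxed sublines; one pool deliberately small (9 individuals),
    emulating the asymmetric low-line pool of the study design."""
    return {
        "HWS55": PoolSpec("high", "g55", 30),
        "LWS55": PoolSpec("low", "g55", 30),
        "HWS40": PoolSpec("high", "g40", 30),
        "LWS40": PoolSpec("low", "g40", 9),
        "HWR9": PoolSpec("high", "relaxed", 30),
        "LWR9": PoolSpec("low", "relaxed", 30),
    }


@dataclass
class ScenarioSpec:
    """A planted locus (or neutral region) with its expected sweep signature."""
    kind: str                 # "duality" | "opposed" | "neutral"
    chrom: str
    start: int
    end: int
    focal_pos: int | None = None   # resolved to the nearest simulated site
    effect: float = 0.0
    site: int | None = None        # site index, filled at build time
    site_down: int | None = None   # second focal site (opposed scenario only)
    expected_class: str | None = None


@dataclass
class SimConfig:
    """Study conditions of the simulated selection experiment.

    Defaults describe a desk-scale rendering of the design: a 2 x 2.5 Mb
    genome with 80,000 segregating founder sites (~8 SNPs/kb after
    filtering, matching the site density of real pooled data), seven
    sublines carrying two mosaic haplotypes each over seven deep ancestral
    haplotypes with block-structured local relatedness (shared-ancestry
    tracts of a few tens of kb), a census of 150 per line with the
    top/bottom half selected each generation under equalized parental
    contributions (the minimized-inbreeding breeding the lines used), 55
    selected generations with relaxed branches split at generation 44 and
    drifted for 9 generations, and pooled sequencing at ~30x within a
    [10, 100] depth band with a small sequencing-error and cross-pool
    contamination noise floor.
    """

    chromosomes: tuple = (("chr1", 2_500_000), ("chr2", 2_500_000))
    n_sites: int = 80_000
    recomb_rate: float = 3e-8          # crossovers per bp per meiosis
    free_recomb: bool = False          # unlinked sites (calibration mode)
    # founder structure
    n_ancestral_haps: int = 7
    n_sublines: int = 7
    subline_haps: int = 2
    founder_recombinations: int = 3600  # historical crossovers across all subline haplotypes
    ancestral_block_len: float = 15_000.0  # mean length of shared-ancestry tracts
    founder_mode: str = "subline_mosaic"   # or "exact_freq"
    p0: float = 0.5                    # initial frequency in exact_freq mode
    # demography and selection
    census_n: int = 150                # diploid individuals per line per generation
    selected_fraction: float = 0.5
    h2: float = 0.5                    # heritability of the selected trait
    n_generations: int = 55
    snapshot_generations: tuple = (40, 55)
    relax_at: int = 44
    relax_generations: int = 9
    transmission: str = "sampling"     # or "balanced" (no-drift limit)
    mating: str = "equalized"          # "equalized" (minimized inbreeding: parents
                                       # contribute equally) or "wright_fisher" (iid parents)
    # trait architecture
    n_causal: int = 4
    effect_mean: float = 0.25          # exponential mean of background effect sizes
    focal_effect: float = 3.0          # effect at planted scenario loci
    scenarios: list = field(default_factory=list)
    # sequencing emulation
    pools: dict = field(default_factory=default_pools)
    depth_mean: float = 30.0
    depth_min: int = 10
    depth_max: int = 100
    seq_error: float = 0.005
    contamination: float = 0.015       # fraction of reads from the cross-pool mixture
                                       # (index misassignment / mapping noise floor)
    seed: int = 0

    def validate(self) -> None:
        if self.n_ancestral_haps < 2:
            raise ValueError("need at least 2 ancestral haplotypes")
        if not (0 < self.selected_fraction <= 1):
            raise ValueError("selected_fraction must be in (0, 1]")
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must be in (0, 1]")
        if self.census_n < 2 or self.n_sites < 1:
            raise ValueError("census_n and n_sites must be positive")
        if self.founder_mode not in ("subline_mosaic", "exact_freq"):
            raise ValueError("founder_mode must be 'subline_mosaic' or 'exact_freq'")
        if self.transmission not in ("sampling", "balanced"):
            raise ValueError("transmission must be 'sampling' or 'balanced'")
        if self.mating not in ("equalized", "wright_fisher"):
            raise ValueError("mating must be 'equalized' or 'wright_fisher'")
        for name, spec in self.pools.items():
            if spec.size > self.census_n:
                raise ValueError(f"pool {name}: pool size {spec.size} exceeds census {self.census_n}")
        for sc in self.scenarios:
            if sc.kind not in ("duality", "opposed", "neutral"):
                raise ValueError(f"unknown scenario kind {sc.kind!r}")

    def chrom_lengths(self) -> dict:
        return {name: int(length) for name, length in self.chromosomes}


def plant_sweep_scenarios(config: SimConfig, kinds: Sequence[str] = ("duality", "opposed", "neutral")) -> SimConfig:
    """Designate planted sweep scenarios, one per chromosome.

    ``duality``: a large positive effect on a single low-frequency founder
    haplotype — the high line is expected to fix the carrier haplotype
    (regional mean H <= 0.1) while the low line keeps segregating.
    ``opposed``: a pair of founder haplotypes with equal-and-opposite
    large effects at nearby private sites — each line is expected to fix
    its own haplotype (both regional heterozygosities <= 0.1).
    ``neutral``: a region with no causal locus, expected below the empirical
    F_ST threshold under drift alone.
    """
    chroms = list(config.chromosomes)
    if len(kinds) > len(chroms):
        raise ValueError(f"{len(kinds)} scenarios but only {len(chroms)} chromosomes")
    scenarios = []
    expected = {"duality": "fixed_high", "opposed": "fixed_both", "neutral": None}
    for kind, (name, length) in zip(kinds, chroms):
        mid = length // 2
        if kind == "duality":
            # the divergent carrier haplotype spans its whole chromosome,
            # and so does the expected sweep signature
            start, end = 1, length
        else:
            half_span = min(500_000, length // 4)
            start, end = mid - half_span, mid + half_span
        scenarios.append(ScenarioSpec(
            kind=kind, chrom=name,
            start=start, end=end,
            focal_pos=None if kind == "neutral" else mid,
            effect=0.0 if kind == "neutral" else config.focal_effect,
            expected_class=expected[kind],
        ))
    cfg = SimConfig(**{**asdict_shallow(config), "scenarios": scenarios})
    cfg.validate()
    return cfg


def asdict_shallow(config: SimConfig) -> dict:
    """Shallow field dict of a config (pools/scenarios kept as objects)."""
    return {f: getattr(config, f) for f in config.__dataclass_fields__}


@dataclass
class Population:
    """A diploid population as a (2N, n_sites) haplotype allele matrix."""
    haps: np.ndarray  # uint8, rows 2i and 2i+1 are individual i

    @property
    def n(self) -> int:
        return self.haps.shape[0] // 2

    def freqs(self) -> np.ndarray:
        return self.haps.mean(axis=0)

    def genotypes(self) -> np.ndarray:
        return self.haps[0::2].astype(np.int16) + self.haps[1::2]

    def copy(self) -> "Population":
        return Population(self.haps.copy())


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""
    chrom: np.ndarray                  # per-site chromosome name
    pos: np.ndarray                    # per-site 1-based position
    founder_freq: np.ndarray           # per-site allele frequency in the founders
    causal_sites: np.ndarray           # site indices carrying effects
    causal_effects: np.ndarray
    scenarios: list                    # ScenarioSpec with resolved focal sites
    paintings: list                    # per subline haplotype: list of (chrom, start, end, ancestral label)
    trajectories: dict = field(default_factory=dict)  # branch -> (n_gen+1, n_sites) float32
    final_freqs: dict = field(default_factory=dict)   # pool snapshot key -> per-site frequency

    def region_sites(self, chrom: str, start: int, end: int) -> np.ndarray:
        return np.flatnonzero((self.chrom == chrom) & (self.pos >= start) & (self.pos <= end))

    def region_mean_het(self, branch: str, generation: int, chrom: str, start: int, end: int) -> float:
        """Realized mean expected heterozygosity 2p(1-p) over a region's sites."""
        p = self.trajectories[branch][generation]
        idx = self.region_sites(chrom, start, end)
        if len(idx) == 0:
            return float("nan")
        h = 2.0 * p[idx] * (1.0 - p[idx])
        return float(np.mean(h))

    def to_json_dict(self, include_trajectories: bool = False) -> dict:
        d = {
            "n_sites": int(len(self.pos)),
            "chrom": self.chrom.tolist(),
            "pos": self.pos.tolist(),
            "founder_freq": np.round(self.founder_freq, 6).tolist(),
            "causal_sites": self.causal_sites.tolist(),
            "causal_effects": np.round(self.causal_effects, 6).tolist(),
            "scenarios": [
                {k: (int(v) if isinstance(v, (int, np.integer)) else v)
                 for k, v in asdict(s).items()}
                for s in self.scenarios
            ],
            "paintings": [
                [[c, int(a), int(b), int(lab)] for (c, a, b, lab) in hap]
                for hap in self.paintings
            ],
            "final_freqs": {k: np.round(v, 6).tolist() for k, v in self.final_freqs.items()},
        }
        if include_trajectories:
            d["trajectories"] = {
                k: np.round(v, 6).tolist() for k, v in self.trajectories.items()
            }
        return d


def write_truth_json(truth: SimTruth, path, include_trajectories: bool = False) -> None:
    with open(path, "wt") as fh:
        json.dump(truth.to_json_dict(include_trajectories), fh)


class ForwardSimulator:
    """Runs the forward model of one selection experiment.

    Usage::

        sim = ForwardSimulator(config)
        table, truth = sim.run()
    """

    def __init__(self, config: SimConfig):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self._init_sites()
        self._founders_built = False

    # -- genome layout -----------------------------------------------------
    def _init_sites(self) -> None:
        cfg = self.config
        lengths = np.array([l for _, l in cfg.chromosomes], dtype=np.int64)
        names = [n for n, _ in cfg.chromosomes]
        # apportion sites to chromosomes proportionally to length
        quota = np.floor(cfg.n_sites * lengths / lengths.sum()).astype(int)
        while quota.sum() < cfg.n_sites:
            quota[int(np.argmax(lengths - quota * lengths.sum() / cfg.n_sites))] += 1
        chrom_col, pos_col, offsets = [], [], [0]
        for name, length, q in zip(names, lengths, quota):
            pos = np.sort(self.rng.choice(length, size=min(q, length), replace=False)) + 1
            chrom_col.extend([name] * len(pos))
            pos_col.append(pos)
            offsets.append(offsets[-1] + len(pos))
        self.site_chrom = np.array(chrom_col, dtype=object)
        self.site_pos = np.concatenate(pos_col) if pos_col else np.array([], dtype=np.int64)
        self.chrom_names = names
        self.chrom_lengths = lengths
        self.chrom_slices = [slice(offsets[i], offsets[i + 1]) for i in range(len(names))]
        self.n_sites = len(self.site_pos)
        # reference/alternative bases per site
        ref_idx = self.rng.integers(0, 4, size=self.n_sites)
        alt_idx = (ref_idx + 1 + self.rng.integers(0, 3, size=self.n_sites)) % 4
        self.ref_base = _BASES[ref_idx]
        self.alt_base = _BASES[alt_idx]

    # -- founders ----------------------------------------------------------
    def build_founders(self):
        """Construct the founder population and its ancestral-haplotype painting.

        Returns ``(population, paintings, subline_hap_matrix)``.
        """
        cfg = self.config
        rng = self.rng
        if cfg.founder_mode == "exact_freq":
            n_ones = int(round(2 * cfg.census_n * cfg.p0))
            haps = np.zeros((2 * cfg.census_n, self.n_sites), dtype=np.uint8)
            for s in range(self.n_sites):
                rows = rng.choice(2 * cfg.census_n, size=n_ones, replace=False)
                haps[rows, s] = 1
            self._finish_founders(Population(haps), paintings=[], subline_haps=None)
            return self.founders, self.paintings, None

        # Ancestral haplotypes with block-structured local relatedness: the
        # genome is tiled by shared-ancestry tracts (exponential lengths) in
        # which the deep haplotypes collapse into a few distinct local
        # variants, so two ancestral haplotypes are often locally identical
        # over long stretches — the substrate of the haploblock mosaic.
        n_anc = cfg.n_ancestral_haps
        anc = np.zeros((n_anc, self.n_sites), dtype=np.uint8)
        for ci, sl in enumerate(self.chrom_slices):
            L = int(self.chrom_lengths[ci])
            cpos = self.site_pos[sl]
            edge = 0.0
            while edge < L:
                nxt = edge + rng.exponential(cfg.ancestral_block_len)
                in_block = np.flatnonzero((cpos > edge) & (cpos <= nxt))
                edge = nxt
                if len(in_block) == 0:
                    continue
                # assign the deep haplotypes to a few distinct local variants
                while True:
                    v = int(rng.integers(2, min(n_anc, 3) + 1))
                    class_of = rng.integers(0, v, size=n_anc)
                    present = np.unique(class_of)
                    if len(present) >= 2:
                        break
                for s in in_block:
                    k = int(rng.integers(1, len(present)))
                    carrier_classes = rng.choice(present, size=k, replace=False)
                    anc[np.isin(class_of, carrier_classes), sl.start + s] = 1

        # subline haplotypes: mosaics of ancestral haplotypes with a fixed
        # total number of historical recombination breakpoints
        n_hap = cfg.n_sublines * cfg.subline_haps
        genome_bp = int(self.chrom_lengths.sum())
        owner = rng.integers(0, n_hap, size=cfg.founder_recombinations)
        bp_global = rng.integers(0, genome_bp, size=cfg.founder_recombinations)
        cum = np.concatenate([[0], np.cumsum(self.chrom_lengths)])
        sub = np.zeros((n_hap, self.n_sites), dtype=np.uint8)
        paintings: list = [[] for _ in range(n_hap)]
        for h in range(n_hap):
            mine = np.sort(bp_global[owner == h])
            label = int(rng.integers(0, n_anc))
            for ci, name in enumerate(self.chrom_names):
                lo, hi = cum[ci], cum[ci + 1]
                local = mine[(mine >= lo) & (mine < hi)] - lo
                seg_edges = np.concatenate([[0], local, [hi - lo]])
                sl = self.chrom_slices[ci]
                cpos = self.site_pos[sl]
                for e in range(len(seg_edges) - 1):
                    a, b = int(seg_edges[e]), int(seg_edges[e + 1])
                    in_seg = (cpos > a) & (cpos <= b)
                    sub[h, sl][in_seg] = anc[label, sl][in_seg]
                    paintings[h].append((name, a + 1, b, label))
                    if e < len(seg_edges) - 2:  # new ancestral label after each breakpoint
                        label = (label + 1 + int(rng.integers(0, n_anc - 1))) % n_anc

        self._apply_scenarios(sub, rng)

        # founder individuals: balanced crosses of the sublines
        haps = np.empty((2 * cfg.census_n, self.n_sites), dtype=np.uint8)
        for row in range(2 * cfg.census_n):
            subline = row % cfg.n_sublines
            hap_in = int(rng.integers(0, cfg.subline_haps))
            haps[row] = sub[subline * cfg.subline_haps + hap_in]
        self._finish_founders(Population(haps), paintings, sub)
        return self.founders, self.paintings, sub

    def _apply_scenarios(self, sub: np.ndarray, rng) -> None:
        """Overwrite focal-site alleles so planted loci sit on the designated
        founder haplotypes, and attach their effects."""
        cfg = self.config
        n_hap = sub.shape[0]
        for sc in cfg.scenarios:
            if sc.kind == "neutral" or sc.focal_pos is None:
                sc.site = None
                continue
            cand = np.flatnonzero(self.site_chrom == sc.chrom)
            if len(cand) == 0:
                raise ValueError(f"scenario on {sc.chrom} but no sites there")
            site = int(cand[np.argmin(np.abs(self.site_pos[cand] - sc.focal_pos))])
            sc.site = site
            sub[:, site] = 0
            if sc.kind == "duality":
                carrier = int(rng.integers(0, n_hap))
                sub[carrier, site] = 1
                self._make_carrier_divergent(sub, carrier, sc.chrom, rng)
            elif sc.kind == "opposed":
                # a pair of opposite-effect haplotypes: one carries a private
                # trait-raising allele, the other a private trait-lowering
                # allele at a nearby site; each line sweeps its own
                hap_up, hap_down = rng.choice(n_hap, size=2, replace=False)
                sub[hap_up, site] = 1
                cand2 = cand[cand != site]
                site2 = int(cand2[np.argmin(np.abs(self.site_pos[cand2] - sc.focal_pos))])
                sc.site_down = site2
                sub[:, site2] = 0
                sub[int(hap_down), site2] = 1

    def _make_carrier_divergent(self, sub: np.ndarray, carrier: int, chrom: str,
                                rng, tract_len: float = 30_000.0,
                                gap_len: float = 45_000.0, density: float = 0.8) -> None:
        """Give the duality carrier an introgression-like divergent haplotype.

        Along the scenario chromosome the carrier receives tracts (exponential
        lengths, ~40% genome coverage) in which most sites carry alleles
        private to it — emulating a founder haplotype from a diverged source
        population, divergent from the rest of the pool at a quarter of its
        sites, as observed for the haplotypes swept in real selected lines.
        """
        ci = self.chrom_names.index(chrom)
        sl = self.chrom_slices[ci]
        cpos = self.site_pos[sl]
        L = int(self.chrom_lengths[ci])
        edge = 0.0
        in_tract = rng.random() < tract_len / (tract_len + gap_len)
        while edge < L:
            # gamma lengths (shape 2) keep tract/gap sizes near their means
            span = rng.gamma(2.0, (tract_len if in_tract else gap_len) / 2.0)
            if in_tract:
                sites = np.flatnonzero((cpos > edge) & (cpos <= edge + span))
                sites = sites[rng.random(len(sites)) < density]
                sub[:, sl.start + sites] = 0
                sub[carrier, sl.start + sites] = 1
            edge += span
            in_tract = not in_tract

    def _finish_founders(self, pop: Population, paintings, subline_haps) -> None:
        cfg = self.config
        self.founders = pop
        self.paintings = paintings
        self.subline_hap_matrix = subline_haps
        self.founder_freq = pop.freqs()

        # trait architecture: planted focal loci plus polygenic background
        sites, effects = [], []
        for sc in cfg.scenarios:
            if sc.site is not None:
                sites.append(sc.site)
                effects.append(sc.effect)
            if sc.site_down is not None:
                sites.append(sc.site_down)
                effects.append(-sc.effect)
        if cfg.n_causal > 0 and cfg.founder_mode == "subline_mosaic":
            # background polygenic loci stay out of the designated scenario regions
            forbidden = np.zeros(self.n_sites, dtype=bool)
            forbidden[list(sites)] = True
            for sc in cfg.scenarios:
                if sc.kind == "neutral":
                    # a neutral designation promises drift-only dynamics for
                    # its whole chromosome: no causal loci may hitchhike there
                    forbidden |= self.site_chrom == sc.chrom
                else:
                    forbidden |= (self.site_chrom == sc.chrom) & \
                        (self.site_pos >= sc.start) & (self.site_pos <= sc.end)
            free = np.flatnonzero(~forbidden)
            pick = self.rng.choice(free, size=min(cfg.n_causal, len(free)), replace=False)
            eff = self.rng.exponential(cfg.effect_mean, size=len(pick))
            eff *= self.rng.choice([-1.0, 1.0], size=len(pick))
            sites.extend(int(s) for s in pick)
            effects.extend(float(e) for e in eff)
        self.causal_sites = np.array(sites, dtype=np.int64)
        self.causal_effects = np.array(effects, dtype=float)

        # environmental variance from founder additive variance and h2
        if len(sites):
            g = pop.genotypes()[:, self.causal_sites].astype(float) @ self.causal_effects
            var_a = float(np.var(g))
        else:
            var_a = 0.0
        self.env_sd = np.sqrt(var_a * (1 - cfg.h2) / cfg.h2) if var_a > 0 else 1.0

    # -- reproduction ------------------------------------------------------
    def _gamete(self, haps: np.ndarray, ind: int, rng) -> np.ndarray:
        """One recombinant gamete from individual ``ind``."""
        cfg = self.config
        out = np.empty(self.n_sites, dtype=np.uint8)
        h0, h1 = haps[2 * ind], haps[2 * ind + 1]
        if cfg.free_recomb:
            mask = rng.integers(0, 2, size=self.n_sites).astype(bool)
            np.copyto(out, h0)
            out[mask] = h1[mask]
            return out
        for ci, sl in enumerate(self.chrom_slices):
            L = int(self.chrom_lengths[ci])
            start = int(rng.integers(0, 2))
            k = int(rng.poisson(cfg.recomb_rate * L))
            if k == 0:
                out[sl] = (h0 if start == 0 else h1)[sl]
            else:
                bps = np.sort(rng.uniform(0, L, size=k))
                phase = (np.searchsorted(bps, self.site_pos[sl].astype(float)) + start) % 2
                out[sl] = np.where(phase == 0, h0[sl], h1[sl])
        return out

    def _gamete_pair(self, haps: np.ndarray, ind: int, rng):
        """Two complementary gametes (balanced transmission, no drift)."""
        cfg = self.config
        g0 = np.empty(self.n_sites, dtype=np.uint8)
        g1 = np.empty(self.n_sites, dtype=np.uint8)
        h0, h1 = haps[2 * ind], haps[2 * ind + 1]
        for ci, sl in enumerate(self.chrom_slices):
            L = int(self.chrom_lengths[ci])
            start = int(rng.integers(0, 2))
            k = int(rng.poisson(cfg.recomb_rate * L))
            if k == 0:
                phase = np.full(sl.stop - sl.start, start)
            else:
                bps = np.sort(rng.uniform(0, L, size=k))
                phase = (np.searchsorted(bps, self.site_pos[sl].astype(float)) + start) % 2
            g0[sl] = np.where(phase == 0, h0[sl], h1[sl])
            g1[sl] = np.where(phase == 0, h1[sl], h0[sl])
        return g0, g1

    def select_generation(self, pop: Population, direction: str, rng=None) -> Population:
        """Produce the next generation under truncation selection.

        ``direction`` is ``"up"``, ``"down"`` or ``"none"`` (relaxed).  The
        trait is the sum of additive effects plus Gaussian environmental
        noise scaled so the founder-generation heritability equals ``h2``;
        the top (or bottom) ``selected_fraction`` of the census become
        parents.  Under ``mating="wright_fisher"`` each offspring gamete
        comes from an independently, uniformly chosen parent (exact binomial
        drift); under ``mating="equalized"`` (default) parents contribute as
        equally as possible, emulating a breeding scheme structured to
        minimize inbreeding and stochastic fixation.
        """
        cfg = self.config
        rng = rng if rng is not None else self.rng
        n = pop.n
        if n == 0:
            raise ValueError("empty population")
        if direction not in ("up", "down", "none"):
            raise ValueError(f"direction must be up/down/none, got {direction!r}")

        if direction == "none" or cfg.selected_fraction >= 1.0:
            parents = np.arange(n)
        else:
            n_sel = int(np.ceil(cfg.selected_fraction * n))
            if n_sel < 2:
                raise ValueError(f"selected count {n_sel} < 2")
            if len(self.causal_sites):
                g = pop.genotypes()[:, self.causal_sites].astype(float) @ self.causal_effects
            else:
                g = np.zeros(n)
            trait = g + rng.normal(0.0, self.env_sd, size=n)
            order = np.argsort(trait, kind="stable")
            chosen = order[-n_sel:] if direction == "up" else order[:n_sel]
            parents = np.sort(chosen)

        if cfg.transmission == "balanced":
            gametes = []
            for ind in parents:
                g0, g1 = self._gamete_pair(pop.haps, int(ind), rng)
                gametes.extend([g0, g1])
            gametes = np.array(gametes)
            perm = rng.permutation(len(gametes))
            return Population(gametes[perm][: 2 * n])

        new = np.empty_like(pop.haps[: 2 * n])
        n_gam = 2 * n
        if cfg.mating == "equalized":
            # minimized-inbreeding breeding: parents contribute as equally as
            # possible to the gamete pool (raises N_e above iid sampling)
            base = np.repeat(parents, n_gam // len(parents))
            rem = n_gam - len(base)
            extra = rng.choice(parents, size=rem, replace=False) if rem else parents[:0]
            gamete_parents = np.concatenate([base, extra])
            rng.shuffle(gamete_parents)
        else:
            gamete_parents = parents[rng.integers(0, len(parents), size=n_gam)]
        for g in range(n_gam):
            new[g] = self._gamete(pop.haps, int(gamete_parents[g]), rng)
        return Population(new)

    # -- sequencing emulation ---------------------------------------------
    def emit_pools(self, populations: dict, rng=None) -> SiteCountTable:
        """Emulate pooled sequencing of the configured pools.

        ``populations`` maps pool name -> :class:`Population`.  For every
        site and pool, ``pool_size`` individuals are sampled without
        replacement, read depth is Poisson(depth_mean) clipped into
        [depth_min, depth_max], reads are binomial in the pool sample
        frequency, and each read miscalls to a uniformly chosen other base
        with probability ``seq_error``.
        """
        cfg = self.config
        rng = rng if rng is not None else self.rng
        pool_ids = list(cfg.pools)
        counts = np.zeros((self.n_sites, len(pool_ids), len(BASE_ORDER)), dtype=np.int64)
        ref_col = np.array([_SYNC_COL[b] for b in self.ref_base])
        alt_col = np.array([_SYNC_COL[b] for b in self.alt_base])
        # fixed assignment of each base's three miscall targets
        others = {b: [c for c in "ATCG" if c != b] for b in "ATCG"}
        # sample pool allele frequencies first: the cross-pool mixture is the
        # source of contaminant reads (index misassignment, mapping noise)
        pool_freq = np.empty((len(pool_ids), self.n_sites))
        for j, name in enumerate(pool_ids):
            spec = cfg.pools[name]
            pop = populations[name]
            if spec.size > pop.n:
                raise ValueError(f"pool {name}: size {spec.size} exceeds census {pop.n}")
            chosen = rng.choice(pop.n, size=spec.size, replace=False)
            rows = np.concatenate([2 * chosen, 2 * chosen + 1])
            pool_freq[j] = pop.haps[rows].mean(axis=0)
        mixture = pool_freq.mean(axis=0)
        for j, name in enumerate(pool_ids):
            p = (1 - cfg.contamination) * pool_freq[j] + cfg.contamination * mixture
            depth = np.clip(
                rng.poisson(cfg.depth_mean, size=self.n_sites), cfg.depth_min, cfg.depth_max
            )
            alt_true = rng.binomial(depth, p)
            ref_true = depth - alt_true
            for base_is_alt, true_counts, col in ((False, ref_true, ref_col), (True, alt_true, alt_col)):
                errs = rng.binomial(true_counts, cfg.seq_error) if cfg.seq_error > 0 else np.zeros_like(true_counts)
                correct = true_counts - errs
                np.add.at(counts[:, j, :], (np.arange(self.n_sites), col), correct)
                if errs.any():
                    e1 = rng.binomial(errs, 1.0 / 3.0)
                    e2 = rng.binomial(errs - e1, 0.5)
                    e3 = errs - e1 - e2
                    src = self.alt_base if base_is_alt else self.ref_base
                    for which, e in enumerate((e1, e2, e3)):
                        tgt = np.array([_SYNC_COL[others[b][which]] for b in src])
                        np.add.at(counts[:, j, :], (np.arange(self.n_sites), tgt), e)
        return SiteCountTable(self.site_chrom, self.site_pos, self.ref_base, counts, pool_ids)

    # -- full run ----------------------------------------------------------
    def run(self):
        """Run the full experiment and return ``(SiteCountTable, SimTruth)``."""
        cfg = self.config
        if not self._founders_built:
            self.build_founders()
            self._founders_built = True
        needed_lines = sorted({spec.line for spec in cfg.pools.values()})
        need_relaxed = any(spec.stage == "relaxed" for spec in cfg.pools.values())

        trajectories: dict = {}
        snapshots: dict = {}
        direction_of = {"high": "up", "low": "down"}
        for line in needed_lines:
            pop = self.founders.copy()
            traj = np.empty((cfg.n_generations + 1, self.n_sites), dtype=np.float32)
            traj[0] = pop.freqs()
            for gen in range(1, cfg.n_generations + 1):
                pop = self.select_generation(pop, direction_of[line])
                traj[gen] = pop.freqs()
                if gen in cfg.snapshot_generations:
                    snapshots[(line, f"g{gen}")] = pop.copy()
                if need_relaxed and gen == cfg.relax_at:
                    rpop = pop.copy()
                    rtraj = np.empty((cfg.relax_generations + 1, self.n_sites), dtype=np.float32)
                    rtraj[0] = rpop.freqs()
                    for rgen in range(1, cfg.relax_generations + 1):
                        rpop = self.select_generation(rpop, "none")
                        rtraj[rgen] = rpop.freqs()
                    snapshots[(line, "relaxed")] = rpop
                    trajectories[f"{line}_relaxed"] = rtraj
            trajectories[line] = traj

        populations = {}
        for name, spec in cfg.pools.items():
            key = (spec.line, spec.stage)
            if key not in snapshots:
                raise ValueError(f"pool {name} needs snapshot {key}, not produced")
            populations[name] = snapshots[key]
        table = self.emit_pools(populations)

        truth = SimTruth(
            chrom=self.site_chrom,
            pos=self.site_pos,
            founder_freq=self.founder_freq,
            causal_sites=self.causal_sites,
            causal_effects=self.causal_effects,
            scenarios=list(cfg.scenarios),
            paintings=self.paintings,
            trajectories=trajectories,
            final_freqs={
                f"{line}_{stage}": pop.freqs()
                for (line, stage), pop in snapshots.items()
            },
        )
        return table, truth


def simulate(config: SimConfig):
    """Convenience wrapper: build a simulator and run it."""
    return ForwardSimulator(config).run()
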