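"""Reading and writing pooled allele-count tables and interval results.

The central container is :class:`SiteCountTable`, a column-oriented table of
per-site, per-pool nucleotide read counts on a reference coordinate system.
The on-disk dialect is the PoPoolation2 "sync" format: tab-separated
``chrom  pos  ref`` followed by one ``A:T:C:G:N:del`` colon-separated count
column per pool.  Sync files carry no header, so the pool order is always
declared by the caller, never inferred.

Coordinates are 1-based inclusive everywhere inside the package; the single
conversion to 0-based half-open happens in :func:`write_regions_bed`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: column order of the six count classes in a sync pool field
BASE_ORDER = ("A", "T", "C", "G", "N", "del")
N_CLASSES = len(BASE_ORDER)


class SyncFormatError(ValueError):
    """Raised when a sync (or genome-table) file violates the format."""


@dataclass
class SiteCountTable:
    """Per-site, per-pool read counts; the atom of all downstream statistics.

    Attributes
    ----------
    chrom : np.ndarray of str, shape (n_sites,)
    pos : np.ndarray of int64, shape (n_sites,)
        1-based site positions, strictly increasing within each chromosome.
    ref : np.ndarray of str, shape (n_sites,)
        Reference base, one of A/C/G/T/N.
    counts : np.ndarray of int64, shape (n_sites, n_pools, 6)
        Read counts in sync class order ``A, T, C, G, N, del``.
    pool_ids : list of str
        Ordered pool labels, e.g. ``["HWS55", "LWS55", ...]``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    counts: np.ndarray
    pool_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim == 2:  # single pool convenience
            self.counts = self.counts[:, None, :]
        self.pool_ids = list(self.pool_ids)
        self.validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_pools(self) -> int:
        return len(self.pool_ids)

    def __len__(self) -> int:
        return self.n_sites

    def __eq__(self, other) -> bool:
        if not isinstance(other, SiteCountTable):
            return NotImplemented
        return (
            self.pool_ids == other.pool_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.counts, other.counts)
        )

    def validate(self) -> None:
        n = self.n_sites
        if not (len(self.chrom) == len(self.ref) == n):
            raise ValueError("chrom/pos/ref length mismatch")
        if self.counts.shape != (n, self.n_pools, N_CLASSES):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({n}, {self.n_pools}, {N_CLASSES})"
            )
        if n and (self.counts < 0).any():
            raise ValueError("negative read counts")
        # positions strictly increasing within each chromosome
        if n > 1:
            same = self.chrom[1:] == self.chrom[:-1]
            if np.any(same & (np.diff(self.pos) <= 0)):
                raise ValueError("positions not strictly increasing within chromosome")

    def depths(self) -> np.ndarray:
        """Per-pool read depth = sum of the six count classes; shape (n_sites, n_pools)."""
        return self.counts.sum(axis=2)

    def pool_index(self, pool: str) -> int:
        try:
            return self.pool_ids.index(pool)
        except ValueError:
            raise KeyError(f"unknown pool {pool!r}; have {self.pool_ids}") from None

    def sort(self) -> "SiteCountTable":
        """Return a copy sorted by (chrom, pos)."""
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return SiteCountTable(
            self.chrom[order], self.pos[order], self.ref[order],
            self.counts[order], self.pool_ids,
        )

    def subset(self, chrom: str, start: int | None = None, end: int | None = None) -> "SiteCountTable":
        """Sites on ``chrom`` with start <= pos <= end (1-based inclusive)."""
        mask = self.chrom == chrom
        if start is not None:
            mask &= self.pos >= start
        if end is not None:
            mask &= self.pos <= end
        return SiteCountTable(
            self.chrom[mask], self.pos[mask], self.ref[mask],
            self.counts[mask], self.pool_ids,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos, "ref": self.ref})
        for j, pid in enumerate(self.pool_ids):
            for k, base in enumerate(BASE_ORDER):
                df[f"{pid}_{base}"] = self.counts[:, j, k]
        return df


@dataclass
class GenomeTable:
    """Chromosome names and lengths (bp); denominators for genome fractions."""

    chroms: list
    lengths: dict

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "GenomeTable":
        chroms, lengths = [], {}
        for name, length in pairs:
            name = str(name)
            length = int(length)
            if name in lengths:
                raise ValueError(f"duplicate chromosome {name!r}")
            if length <= 0:
                raise ValueError(f"non-positive length for {name!r}")
            chroms.append(name)
            lengths[name] = length
        return cls(chroms, lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())


# ---------------------------------------------------------------------------
# sync I/O


def _parse_pool_field(field_str: str, lineno: int) -> list:
    parts = field_str.split(":")
    if len(parts) != N_CLASSES:
        raise SyncFormatError(
            f"line {lineno}: pool field {field_str!r} has {len(parts)} classes, expected {N_CLASSES}"
        )
    try:
        return [int(p) for p in parts]
    except ValueError:
        raise SyncFormatError(f"line {lineno}: non-numeric count in {field_str!r}") from None


def read_sync(path, pool_ids: Sequence[str]) -> SiteCountTable:
    """Read a PoPoolation2 sync file into a :class:`SiteCountTable`.

    ``pool_ids`` declares the order of the per-pool count columns (sync has
    no header).  A column-count mismatch or a malformed count raises
    :class:`SyncFormatError` naming the offending line.  Rows are returned
    sorted by (chrom, pos).
    """
    pool_ids = list(pool_ids)
    n_pools = len(pool_ids)
    chroms, poss, refs, counts = [], [], [], []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            if len(fields) != 3 + n_pools:
                raise SyncFormatError(
                    f"line {lineno}: {len(fields) - 3} pool columns, expected {n_pools}"
                )
            chroms.append(fields[0])
            try:
                poss.append(int(fields[1]))
            except ValueError:
                raise SyncFormatError(f"line {lineno}: non-integer position {fields[1]!r}") from None
            refs.append(fields[2])
            counts.append([_parse_pool_field(f, lineno) for f in fields[3:]])
    chrom_a = np.array(chroms, dtype=object)
    pos_a = np.array(poss, dtype=np.int64)
    ref_a = np.array(refs, dtype=object)
    counts_a = np.array(counts, dtype=np.int64).reshape(len(poss), n_pools, N_CLASSES)
    order = np.lexsort((pos_a, chrom_a.astype(str)))
    return SiteCountTable(chrom_a[order], pos_a[order], ref_a[order],
                          counts_a[order], pool_ids)


def write_sync(table: SiteCountTable, path) -> None:
    """Write ``table`` as a header-less sync file (inverse of :func:`read_sync`)."""
    with open(path, "wt") as fh:
        for i in range(table.n_sites):
            pools = "\t".join(
                ":".join(str(c) for c in table.counts[i, j])
                for j in range(table.n_pools)
            )
            row = f"{table.chrom[i]}\t{table.pos[i]}\t{table.ref[i]}"
            fh.write(row + ("\t" + pools if table.n_pools else "") + "\n")


# ---------------------------------------------------------------------------
# genome table I/O


def read_genome_table(path) -> GenomeTable:
    """Read a two-column TSV of chromosome name and length (bp)."""
    pairs = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise SyncFormatError(f"line {lineno}: expected 2 columns, got {len(fields)}")
            try:
                pairs.append((fields[0], int(fields[1])))
            except ValueError:
                raise SyncFormatError(f"line {lineno}: non-integer length {fields[1]!r}") from None
    return GenomeTable.from_pairs(pairs)


def write_genome_table(genome: GenomeTable, path) -> None:
    with open(path, "wt") as fh:
        for c in genome.chroms:
            fh.write(f"{c}\t{genome.lengths[c]}\n")


# ---------------------------------------------------------------------------
# results output


def write_regions_bed(regions, path, genome: GenomeTable | None = None) -> None:
    """Write differentiated regions as BED6.

    Internal spans are 1-based inclusive; BED is 0-based half-open, so
    ``start_bed = start - 1`` and ``end_bed = end``.  The name column is the
    duality class, the score is the mean member-window F_ST scaled to 0-1000
    and truncated into that range.
    """
    rows = []
    for r in regions:
        if genome is not None:
            if r.chrom not in genome:
                raise ValueError(f"region chromosome {r.chrom!r} not in genome table")
            if r.start < 1 or r.end > genome[r.chrom]:
                raise ValueError(
                    f"region {r.chrom}:{r.start}-{r.end} outside chromosome bounds"
                )
        fst = r.mean_fst if r.mean_fst is not None and np.isfinite(r.mean_fst) else 0.0
        score = int(min(1000, max(0, round(fst * 1000))))
        rows.append((r.chrom, r.start - 1, r.end, r.duality_class or ".", score, "."))
    rows.sort(key=lambda t: (t[0], t[1]))
    with open(path, "wt") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_windows_tsv(windows: pd.DataFrame, path) -> None:
    """Write the window statistics table as TSV (NaN rendered empty)."""
    windows.to_csv(path, sep="\t", index=False, na_rep="")


def read_windows_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
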