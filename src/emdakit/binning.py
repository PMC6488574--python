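"""Dynamic genome binning and per-bin read counting.

Bins hold (approximately) equal uniquely-mappable content rather than equal
genomic span: in poorly-mappable territory bins stretch so that each bin
receives the same expected number of uniquely mapped reads under uniform
coverage.  The per-bin quota is ``target_size x genome-wide mean
mappability``, so on a perfectly mappable genome bins span exactly
``target_size`` bases (the 50-kb default mirrors common scWGS practice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = ["BinSet", "BinCounts", "build_dynamic_bins", "count_reads", "dropout_ratio"]


@dataclass
class BinSet:
    """Ordered genomic bins with mappable content and GC.

    ``bins`` columns: chrom, start, end, mappable, gc.  Bins tile each
    chromosome contiguously (half-open, 0-based).
    """

    bins: pd.DataFrame
    target_bin_size: int

    def __post_init__(self) -> None:
        b = self.bins
        for chrom, grp in b.groupby("chrom", sort=False):
            s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
            if not ((e > s).all() and (s[1:] == e[:-1]).all()):
                raise ValueError(f"bins on {chrom} do not tile contiguously")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    @property
    def chrom_labels(self) -> np.ndarray:
        return self.bins["chrom"].to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.bins["gc"].to_numpy(dtype=float)


@dataclass
class BinCounts:
    """Per-bin uniquely-mapped read counts for one sample."""

    sample_id: str
    counts: np.ndarray
    total_reads: int
    mapped_reads: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative bin counts")
        if not self.counts.sum() <= self.mapped_reads <= self.total_reads:
            raise ValueError("sum(counts) <= mapped_reads <= total_reads violated")


def build_dynamic_bins(genome: GenomeModel, target_size: int = 50_000) -> BinSet:
    """Partition the genome into bins of equal uniquely-mappable content.

    Windows of the mappability track are accumulated until the bin's
    mappable content reaches the quota ``target_size x mean mappability``;
    per-bin GC is the mappability-weighted mean over the bin's windows.
    A chromosome's final partial bin is kept if it holds at least half the
    quota, otherwise merged into its left neighbour.  Chromosomes with no
    mappable content yield no bins (with a warning).
    """
    w = genome.window
    if target_size < w:
        raise ValueError("target_size must be >= the mappability window resolution")
    total_mappable = sum(genome.mappability[c].sum() * w for c, _ in genome.chromosomes)
    quota = target_size * (total_mappable / genome.total_length)
    if quota <= 0:
        raise ValueError("genome has zero mappable content")

    rows = []
    for chrom, length in genome.chromosomes:
        mp = genome.mappability[chrom]
        gc = genome.gc[chrom]
        if mp.sum() == 0:
            warnings.warn(f"chromosome {chrom} has zero mappable content; no bins")
            continue
        chrom_rows = []
        acc_map = acc_gc = 0.0
        bin_start = 0
        for i in range(len(mp)):
            acc_map += mp[i] * w
            acc_gc += mp[i] * w * gc[i]
            end = (i + 1) * w
            if acc_map >= quota - 1e-9:
                chrom_rows.append(
                    (chrom, bin_start, end, acc_map,
                     acc_gc / acc_map if acc_map > 0 else np.nan)
                )
                bin_start, acc_map, acc_gc = end, 0.0, 0.0
        if bin_start < length:  # trailing partial bin
            gmean = acc_gc / acc_map if acc_map > 0 else np.nan
            if acc_map >= 0.5 * quota or not chrom_rows:
                chrom_rows.append((chrom, bin_start, length, acc_map, gmean))
            else:
                c, s, e, m, g = chrom_rows[-1]
                tot = m + acc_map
                gnew = (g * m + (acc_gc if acc_map > 0 else 0.0)) / tot
                chrom_rows[-1] = (c, s, length, tot, gnew)
        rows.extend(chrom_rows)

    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "mappable", "gc"])
    return BinSet(bins=bins, target_bin_size=target_size)


def count_reads(
    binset: BinSet,
    alignments: pd.DataFrame,
    mapq_min: int = 15,
    sample_id: str = "sample",
    total_reads: int | None = None,
    by: str = "start",
) -> BinCounts:
    """Count uniquely mapped reads per bin.

    ``alignments`` is a BED-like table with columns chrom, start, end, mapq;
    "uniquely mapped" is operationalized as ``mapq >= mapq_min`` (default
    15).  Each passing record increments the bin containing its start
    coordinate (or midpoint with ``by="midpoint"``); records on chromosomes
    absent from the bin set are skipped and counted, never an error.
    """
    if by not in ("start", "midpoint"):
        raise ValueError("by must be 'start' or 'midpoint'")
    aln = alignments
    if "mapq" in aln.columns:
        aln = aln[aln["mapq"].to_numpy() >= mapq_min]
    counts = np.zeros(len(binset), dtype=np.int64)
    n_skipped = 0
    bin_chrom = binset.bins["chrom"].to_numpy()
    for chrom, grp in aln.groupby("chrom", sort=False):
        idx = np.flatnonzero(bin_chrom == chrom)
        if len(idx) == 0:
            n_skipped += len(grp)
            continue
        starts = binset.bins["start"].to_numpy()[idx]
        chrom_end = int(binset.bins["end"].to_numpy()[idx][-1])
        pos = grp["start"].to_numpy()
        if by == "midpoint":
            pos = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
        inside = (pos >= starts[0]) & (pos < chrom_end)
        n_skipped += int((~inside).sum())
        which = np.searchsorted(starts, pos[inside], side="right") - 1
        np.add.at(counts, idx[which], 1)
    mapped = len(aln)  # records passing the quality gate are mapped reads
    if total_reads is None:
        total_reads = len(alignments)
    return BinCounts(
        sample_id=sample_id,
        counts=counts,
        total_reads=max(total_reads, mapped),
        mapped_reads=mapped,
        n_skipped=n_skipped,
    )


def dropout_ratio(counts: BinCounts | np.ndarray) -> float:
    """Fraction of bins with zero uniquely mapped reads (genome-coverage proxy)."""
    arr = counts.counts if isinstance(counts, BinCounts) else np.asarray(counts)
    if arr.size == 0:
        raise ValueError("empty bin set")
    return float((arr == 0).sum() / arr.size)
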