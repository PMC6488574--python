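"""Readers and writers for the on-disk formats.

Genomic interval files (bins, truth profiles, alignments, segments) are
BED-style: 0-based, half-open, tab-separated.  Tabular outputs are TSV with
a header line; lines starting with ``#`` are comments.  Allele-depth tables
use 1-based positions (VCF convention); VCF input is read with cyvcf2 and
only the per-allele depths (AD) are extracted.  Every writer can attach a
run-metadata JSON (version, seed, config hash) next to its output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import BinCounts, BinSet
from .genome import TruthProfile
from .snv import SITE_COLUMNS

__all__ = [
    "read_bins_bed", "write_bins_bed",
    "read_counts_tsv", "write_counts_tsv",
    "read_truth_bed", "write_truth_bed",
    "read_alignments_bed",
    "read_allele_table", "write_allele_table", "read_vcf_allele_depths",
    "write_segments", "write_run_metadata", "config_hash",
]

_TSV = dict(sep="\t", comment="#")


def write_bins_bed(binset: BinSet, path: str | Path) -> None:
    binset.bins.to_csv(path, sep="\t", index=False)


def read_bins_bed(path: str | Path, target_bin_size: int | None = None) -> BinSet:
    """Read a bin BED/TSV (chrom, start, end[, mappable, gc]).

    Externally supplied bin files (e.g. precomputed hg19 dynamic bins) may
    lack mappable/GC columns; mappable defaults to the bin span and GC to
    NaN (GC correction then requires a GC column).
    """
    df = pd.read_csv(path, **_TSV)
    if "mappable" not in df.columns:
        df["mappable"] = (df["end"] - df["start"]).astype(float)
    if "gc" not in df.columns:
        df["gc"] = np.nan
    if target_bin_size is None:
        target_bin_size = int(np.median(df["end"] - df["start"]))
    return BinSet(bins=df[["chrom", "start", "end", "mappable", "gc"]],
                  target_bin_size=target_bin_size)


def write_counts_tsv(counts: BinCounts, binset: BinSet, path: str | Path) -> None:
    df = binset.bins[["chrom", "start", "end"]].copy()
    df["count"] = counts.counts
    with open(path, "w") as fh:
        fh.write(f"# sample_id={counts.sample_id} total_reads={counts.total_reads} "
                 f"mapped_reads={counts.mapped_reads}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path: str | Path, sample_id: str | None = None) -> BinCounts:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        meta = dict(kv.split("=") for kv in first[1:].split() if "=" in kv)
    df = pd.read_csv(path, **_TSV)
    counts = df["count"].to_numpy(dtype=np.int64)
    mapped = int(meta.get("mapped_reads", counts.sum()))
    total = int(meta.get("total_reads", mapped))
    return BinCounts(
        sample_id=sample_id or meta.get("sample_id", "sample"),
        counts=counts,
        total_reads=max(total, mapped),
        mapped_reads=max(mapped, int(counts.sum())),
    )


def write_truth_bed(truth: TruthProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# baseline_ploidy={truth.baseline_ploidy}\n")
        for chrom, start, end, cn in truth.events:
            fh.write(f"{chrom}\t{start}\t{end}\t{cn}\n")


def read_truth_bed(path: str | Path) -> TruthProfile:
    baseline = 2
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "baseline_ploidy=" in line:
                    baseline = int(line.split("baseline_ploidy=")[1].split()[0])
                continue
            chrom, start, end, cn = line.split("\t")[:4]
            events.append((chrom, int(start), int(end), int(cn)))
    return TruthProfile(events=events, baseline_ploidy=baseline)


def read_alignments_bed(path: str | Path) -> pd.DataFrame:
    """Read 6-column BED alignments; the score column carries MAPQ."""
    df = pd.read_csv(path, **_TSV, header=None if _headerless(path) else 0)
    if df.columns.dtype != object or "chrom" not in df.columns:
        names = ["chrom", "start", "end", "name", "mapq", "strand"][: df.shape[1]]
        df.columns = names
    if "mapq" not in df.columns:
        df["mapq"] = 60
    return df[[c for c in ("chrom", "start", "end", "mapq") if c in df.columns]]


def _headerless(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return not line.lower().startswith("chrom")
    return True


def write_allele_table(table: pd.DataFrame, path: str | Path) -> None:
    table[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_allele_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, **_TSV)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[SITE_COLUMNS + [c for c in df.columns if c not in SITE_COLUMNS]]


def read_vcf_allele_depths(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Extract per-site ref/alt depths (AD field) for one sample of a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    idx = samples.index(sample) if sample is not None else 0
    rows = []
    for var in vcf:
        if not var.ALT:
            continue
        ad = var.format("AD")
        if ad is None:
            continue
        depths = ad[idx]
        ref_d = int(depths[0]) if depths[0] >= 0 else 0
        alt_d = int(depths[1]) if len(depths) > 1 and depths[1] >= 0 else 0
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], ref_d, alt_d))
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_segments(segset, binset: BinSet, path: str | Path, sample_id: str = "sample") -> None:
    """SEG-like TSV with genomic coordinates of each segment."""
    bins = binset.bins
    rows = []
    for row in segset.segments.itertuples():
        rows.append(
            {
                "sample_id": sample_id,
                "chrom": row.chrom,
                "start": int(bins["start"].iloc[row.start_bin]),
                "end": int(bins["end"].iloc[row.end_bin - 1]),
                "n_bins": row.n_bins,
                "mean_cn": row.mean,
                "integer_cn": row.integer_cn,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_run_metadata(path: str | Path, config: dict, seed: int | None = None,
                       extra: dict | None = None) -> None:
    from . import __version__

    meta = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")
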