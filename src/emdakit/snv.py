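"""Heterozygosity, allele drop-out and coverage breadth from allele depths.

Works on per-site allele-depth tables (chrom, pos, ref, alt, ref_depth,
alt_depth; positions 1-based as in VCF) rather than raw reads: the upstream
trimming/alignment/genotyping chain is standard published tooling.  A site
is heterozygous when its total depth and minor allele frequency clear the
thresholds — MAF >= 5% at depth >= 5 for amplified single cells, MAF >= 20%
at depth >= 30 for unamplified bulk (the bulk rule is strictly nested in
the single-cell rule).  Allele drop-out is scored against bulk-called het
sites: a covered site drops out when either allele lacks supporting reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HetThresholds",
    "SINGLE_CELL_THRESHOLDS",
    "BULK_THRESHOLDS",
    "ADOReport",
    "call_het_sites",
    "ado_rate",
    "coverage_breadth",
]

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_depth", "alt_depth"]


@dataclass(frozen=True)
class HetThresholds:
    """Minor-allele-frequency and depth gates for heterozygous calls."""

    maf_min: float
    depth_min: int

    def __post_init__(self) -> None:
        if not 0 < self.maf_min <= 0.5:
            raise ValueError("maf_min must be in (0, 0.5]")
        if self.depth_min < 1:
            raise ValueError("depth_min must be >= 1")


SINGLE_CELL_THRESHOLDS = HetThresholds(maf_min=0.05, depth_min=5)
BULK_THRESHOLDS = HetThresholds(maf_min=0.20, depth_min=30)


@dataclass
class ADOReport:
    """Allele-dropout summary of a single cell against bulk het sites.

    At the primary depth cutoff: ``n_covered`` bulk-het sites reach the
    cutoff in the cell, ``n_both_alleles`` of them show both alleles, and
    ``ado_rate = 1 - n_both_alleles / n_covered``.  ``by_cutoff`` repeats
    the computation over a ladder of depth cutoffs; ``breadth`` gives the
    covered fraction of bulk het sites per cutoff.
    """

    sample_id: str
    n_bulk_het: int
    n_covered: int
    n_both_alleles: int
    ado_rate: float
    depth_cutoff: int
    alt_evidence_min: int
    by_cutoff: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_bulk_het": self.n_bulk_het,
            "n_covered": self.n_covered,
            "n_both_alleles": self.n_both_alleles,
            "ado_rate": self.ado_rate,
            "depth_cutoff": self.depth_cutoff,
            "alt_evidence_min": self.alt_evidence_min,
            "by_cutoff": self.by_cutoff.to_dict(orient="records"),
        }


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SITE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allele table missing columns: {missing}")
    if (table[["ref_depth", "alt_depth"]].to_numpy() < 0).any():
        raise ValueError("negative allele depths")
    return table


def call_het_sites(
    table: pd.DataFrame,
    thresholds: HetThresholds = SINGLE_CELL_THRESHOLDS,
) -> pd.DataFrame:
    """Heterozygous sites of an allele-depth table.

    A site is heterozygous when total depth >= depth_min and
    min(ref, alt) / total >= maf_min, both inclusive.
    """
    table = _validate(table)
    ref = table["ref_depth"].to_numpy(dtype=float)
    alt = table["alt_depth"].to_numpy(dtype=float)
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, np.minimum(ref, alt) / np.maximum(total, 1), 0.0)
    het = (total >= thresholds.depth_min) & (maf >= thresholds.maf_min)
    return table[het].reset_index(drop=True)


def _site_keys(table: pd.DataFrame) -> set[tuple]:
    return set(zip(table["chrom"], table["pos"]))


def ado_rate(
    cell: pd.DataFrame,
    bulk_het: pd.DataFrame | set,
    depth_cutoff: int = 5,
    alt_evidence_min: int = 1,
    depth_cutoffs: list[int] | None = None,
    sample_id: str = "cell",
    region_mask: list[tuple[str, int, int]] | None = None,
) -> ADOReport:
    """Allele drop-out of a cell over bulk-called heterozygous sites.

    Sites in ``bulk_het`` (a table or a set of (chrom, pos) keys) absent
    from the cell table count as depth 0.  A covered site (cell depth >=
    ``depth_cutoff``) exhibits drop-out when either allele has fewer than
    ``alt_evidence_min`` supporting reads.  ``region_mask`` optionally
    restricts scoring to 0-based half-open genomic intervals (e.g. the
    diploid segments of the cell's copy-number profile).
    """
    cell = _validate(cell)
    keys = bulk_het if isinstance(bulk_het, set) else _site_keys(bulk_het)
    if not keys:
        raise ValueError("bulk het site set is empty")
    if region_mask is not None:
        keys = {
            (c, p) for c, p in keys
            if any(c == mc and ms < p <= me for mc, ms, me in region_mask)
        }
        if not keys:
            raise ValueError("no bulk het sites inside the region mask")

    in_bulk = cell.apply(lambda r: (r["chrom"], r["pos"]) in keys, axis=1) \
        if len(cell) else pd.Series([], dtype=bool)
    sub = cell[in_bulk.to_numpy()] if len(cell) else cell
    ref = sub["ref_depth"].to_numpy(dtype=int) if len(sub) else np.array([], int)
    alt = sub["alt_depth"].to_numpy(dtype=int) if len(sub) else np.array([], int)
    depth = ref + alt
    n_bulk = len(keys)

    cutoffs = sorted(set((depth_cutoffs or []) + [depth_cutoff]))
    rows = []
    for c in cutoffs:
        covered = depth >= c
        n_cov = int(covered.sum())
        both = covered & (ref >= alt_evidence_min) & (alt >= alt_evidence_min)
        n_both = int(both.sum())
        rows.append(
            {
                "depth_cutoff": c,
                "n_covered": n_cov,
                "n_both_alleles": n_both,
                "ado_rate": 1.0 - n_both / n_cov if n_cov else np.nan,
                "breadth": n_cov / n_bulk,
            }
        )
    by_cutoff = pd.DataFrame(rows)
    main = by_cutoff[by_cutoff["depth_cutoff"] == depth_cutoff].iloc[0]
    if main["n_covered"] == 0:
        raise ValueError(
            f"no bulk het site reaches depth {depth_cutoff} in the cell "
            f"({n_bulk} bulk het sites considered)"
        )
    return ADOReport(
        sample_id=sample_id,
        n_bulk_het=n_bulk,
        n_covered=int(main["n_covered"]),
        n_both_alleles=int(main["n_both_alleles"]),
        ado_rate=float(main["ado_rate"]),
        depth_cutoff=depth_cutoff,
        alt_evidence_min=alt_evidence_min,
        by_cutoff=by_cutoff,
    )


def coverage_breadth(
    cell: pd.DataFrame,
    target_sites: pd.DataFrame | set,
    depth_cutoffs: list[int] = (1, 5, 10, 30),
) -> pd.DataFrame:
    """Fraction of target sites reaching each depth cutoff in the cell.

    Target sites absent from the cell table count as depth 0; breadth is
    non-increasing in the cutoff.
    """
    cell = _validate(cell)
    keys = target_sites if isinstance(target_sites, set) else _site_keys(target_sites)
    if not keys:
        raise ValueError("target site set is empty")
    depth_by_key = {
        (r.chrom, r.pos): r.ref_depth + r.alt_depth for r in cell.itertuples()
    }
    depths = np.array([depth_by_key.get(k, 0) for k in keys])
    rows = [
        {"depth_cutoff": int(c), "breadth": float((depths >= c).mean())}
        for c in depth_cutoffs
    ]
    return pd.DataFrame(rows)
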