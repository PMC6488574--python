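"""Copy-number calling: GC correction, absolute ploidy, integer profiles.

The chain is the standard one for shallow single-cell WGS: per-bin counts
are corrected for GC bias by locally weighted regression, normalized to
mean 1, scaled to absolute copy number by a grid search over candidate
ploidies (ACD: the candidate minimizing the squared distance of every bin
to its nearest integer wins), segmented by CBS, and rounded per segment to
integer copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .binning import BinCounts, BinSet
from .genome import TruthProfile
from .segment import SegmentSet, cbs_segment

__all__ = [
    "CopyNumberProfile",
    "gc_correct",
    "acd_ploidy",
    "integer_profile",
    "detection_rate",
    "call_profile",
]


@dataclass
class CopyNumberProfile:
    """Per-bin copy-number calls for one cell.

    ``raw_ratio`` is the GC-corrected, mean-1 normalized count ratio
    (0 at dropout bins); ``scaled_cn = raw_ratio * ploidy``;
    ``integer_cn`` carries the per-bin integer call with NaN at dropout
    bins; ``residual_curve`` is the (candidate ploidy, residual) table of
    the ACD search.
    """

    sample_id: str
    binset: BinSet
    raw_ratio: np.ndarray
    ploidy: float
    scaled_cn: np.ndarray
    integer_cn: np.ndarray
    residual_curve: pd.DataFrame
    segments: SegmentSet | None = None
    dropout_mask: np.ndarray | None = None
    gc_diagnostic: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.binset.bins[["chrom", "start", "end"]].copy()
        df["raw_ratio"] = self.raw_ratio
        df["scaled_cn"] = self.scaled_cn
        df["integer_cn"] = self.integer_cn
        return df


def gc_correct(
    counts: BinCounts | np.ndarray,
    binset: BinSet,
    span: float = 0.3,
) -> tuple[np.ndarray, pd.DataFrame]:
    """LOWESS GC correction of per-bin counts.

    Fits count ~ GC over non-dropout bins with locally weighted regression
    (fraction ``span``), divides each count by its fitted value
    (multiplicative bias model) and renormalizes non-dropout bins to mean 1.
    Dropout bins get corrected value 0 and are excluded from the fit.

    Returns ``(ratio, diagnostic)`` where the diagnostic table holds the
    pre-correction trend (gc, count, fitted) for QC plotting.
    """
    arr = counts.counts if isinstance(counts, BinCounts) else np.asarray(counts, float)
    if len(arr) != len(binset):
        raise ValueError("counts not aligned to the bin set")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    gc = binset.gc
    dropout = arr == 0
    keep = ~dropout & np.isfinite(gc)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 non-dropout bins; cannot fit GC trend")

    if np.ptp(gc[keep]) < 1e-9:  # flat GC track: nothing to correct
        fitted = np.full(int(keep.sum()), arr[keep].mean(), dtype=float)
    else:
        fitted = lowess(arr[keep].astype(float), gc[keep], frac=span,
                        return_sorted=False)
    fitted = np.maximum(fitted, 1e-12)
    ratio = np.zeros(len(arr), dtype=float)
    ratio[keep] = arr[keep] / fitted
    ratio[keep] /= ratio[keep].mean()
    diagnostic = pd.DataFrame({"gc": gc[keep], "count": arr[keep], "fitted": fitted})
    return ratio, diagnostic


def acd_ploidy(
    raw_ratio: np.ndarray,
    grid: tuple[float, float, float] = (1.5, 6.0, 0.05),
    dropout_mask: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Absolute copy-number determination by residual minimization.

    For each candidate ploidy P on the grid the residual is
    ``R(P) = sum_b (P r_b - round(P r_b))^2`` over non-dropout bins; the
    candidate with the smallest residual is the ploidy, ties broken toward
    the smallest P (integer multiples of the true ploidy fit equally well).
    Returns the winning ploidy and the full residual curve.
    """
    lo, hi, step = grid
    if not (1.0 <= lo <= hi <= 8.0) or step <= 0:
        raise ValueError("ploidy grid must lie within [1, 8] with positive step")
    candidates = np.round(np.arange(lo, hi + step / 2, step), 10)
    if len(candidates) == 0:
        raise ValueError("empty ploidy grid")
    r = np.asarray(raw_ratio, dtype=float)
    if dropout_mask is None:
        dropout_mask = r == 0
    r = r[~dropout_mask]
    if r.size == 0:
        raise ValueError("no non-dropout bins")
    scaled = candidates[:, None] * r[None, :]
    resid = ((scaled - np.rint(scaled)) ** 2).sum(axis=1)
    best = resid.min()
    ploidy = float(candidates[resid <= best + 1e-9][0])
    curve = pd.DataFrame({"ploidy": candidates, "residual": resid})
    return ploidy, curve


def _round_half_away(x):
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def integer_profile(
    segments: SegmentSet,
    n_bins: int,
    dropout_mask: np.ndarray | None = None,
    per_bin: bool = False,
    scaled_cn: np.ndarray | None = None,
) -> np.ndarray:
    """Per-bin integer copy numbers from a segmentation.

    Every bin inherits ``round(segment mean)`` with halves rounded away
    from zero; dropout bins are flagged missing (NaN).  With
    ``per_bin=True`` each bin is instead rounded from its own scaled value
    (the bulk-style path), requiring ``scaled_cn``.
    """
    out = np.full(n_bins, np.nan)
    if per_bin:
        if scaled_cn is None:
            raise ValueError("per_bin rounding requires scaled_cn")
        out = _round_half_away(np.asarray(scaled_cn, float))
    else:
        for row in segments.segments.itertuples():
            out[row.start_bin:row.end_bin] = _round_half_away(row.mean)
    if dropout_mask is not None:
        out[dropout_mask] = np.nan
    return out


def detection_rate(
    cell_integer_cn: np.ndarray,
    reference_events: TruthProfile | list[tuple[str, int, int, int]],
    binset: BinSet,
    min_overlap: float = 0.5,
) -> float:
    """Fraction of reference CNV events recovered in a cell's profile.

    An event counts as detected when at least ``min_overlap`` of the bins
    whose midpoints fall inside the event carry the event's integer copy
    number in the cell.
    """
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    events = (
        reference_events.events
        if isinstance(reference_events, TruthProfile)
        else list(reference_events)
    )
    if not events:
        raise ValueError("no reference events to score")
    cn = np.asarray(cell_integer_cn, dtype=float)
    bins = binset.bins
    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    bin_chrom = bins["chrom"].to_numpy()
    detected = 0
    for chrom, start, end, value in events:
        member = (bin_chrom == chrom) & (mid >= start) & (mid < end)
        if not member.any():
            continue
        hits = cn[member] == value
        if hits.mean() >= min_overlap:
            detected += 1
    return detected / len(events)


def call_profile(
    counts: BinCounts,
    binset: BinSet,
    gc_span: float = 0.3,
    ploidy_grid: tuple[float, float, float] = (1.5, 6.0, 0.05),
    cbs_alpha: float = 0.01,
    cbs_nperm: int = 1000,
    seed: int = 0,
    segment_level_rounding: bool = True,
) -> CopyNumberProfile:
    """Full calling chain: GC-correct, normalize, segment, ACD-scale, round.

    The ratio series is segmented first (the CBS statistic and its
    permutation test are scale-invariant, so segmenting before or after
    ploidy scaling yields identical breakpoints) and the ACD search runs on
    the per-bin segment means: per-bin noise enters the residual as
    ``(P sigma)^2`` per bin, which tilts the raw-bin search toward small P,
    while segment means suppress that term by the segment length.
    """
    ratio, diagnostic = gc_correct(counts, binset, span=gc_span)
    dropout_mask = ratio == 0
    segments = cbs_segment(
        ratio, binset.chrom_labels, alpha=cbs_alpha,
        n_permutations=cbs_nperm, seed=seed, dropout_mask=dropout_mask,
    )
    seg_mean = np.zeros_like(ratio)
    for row in segments.segments.itertuples():
        seg_mean[row.start_bin:row.end_bin] = row.mean
    seg_mean[dropout_mask] = 0.0
    ploidy, curve = acd_ploidy(seg_mean, ploidy_grid, dropout_mask)
    scaled = ratio * ploidy
    segments.segments["mean"] = segments.segments["mean"] * ploidy
    segments.segments["integer_cn"] = _round_half_away(
        segments.segments["mean"].to_numpy()
    ).astype(int)
    integer_cn = integer_profile(
        segments, len(binset), dropout_mask,
        per_bin=not segment_level_rounding, scaled_cn=scaled,
    )
    return CopyNumberProfile(
        sample_id=counts.sample_id,
        binset=binset,
        raw_ratio=ratio,
        ploidy=ploidy,
        scaled_cn=scaled,
        integer_cn=integer_cn,
        residual_curve=curve,
        segments=segments,
        dropout_mask=dropout_mask,
        gc_diagnostic=diagnostic,
    )
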