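"""Evenness and quality metrics for amplified single-cell profiles.

MAD here is the scWGS evenness metric: the average (or median) absolute
difference of copy number between adjacent bins *within* chromosomes, so
aneuploidy and large CNVs do not inflate it — only bin-to-bin technical
noise does.  Cells pass QC when MAD <= 1 and dropout ratio <= 0.5
(inclusive).  Coverage uniformity over the whole genome is summarized by
the Lorenz curve of bin counts and its Gini coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binning import BinCounts

__all__ = ["QCReport", "mad_adjacent", "qc_gate", "lorenz_curve", "qc_report"]

MAD_THRESHOLD = 1.0
DROPOUT_THRESHOLD = 0.5


@dataclass
class QCReport:
    """Per-cell quality verdict and evenness summary."""

    sample_id: str
    mad: float
    mad_mode: str
    dropout: float
    passed: bool
    reasons: list[str]
    mad_threshold: float = MAD_THRESHOLD
    dropout_threshold: float = DROPOUT_THRESHOLD
    lorenz: np.ndarray | None = None
    gini: float | None = None

    def to_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "mad": self.mad,
            "mad_mode": self.mad_mode,
            "dropout": self.dropout,
            "passed": bool(self.passed),
            "reasons": self.reasons,
            "mad_threshold": self.mad_threshold,
            "dropout_threshold": self.dropout_threshold,
        }
        if self.gini is not None:
            d["gini"] = self.gini
        return d


def mad_adjacent(
    values: np.ndarray,
    chrom_labels: np.ndarray,
    mode: str = "mean",
    dropout_mask: np.ndarray | None = None,
) -> float:
    """Adjacent-bin absolute copy-number difference, averaged.

    Differences are taken between originally-adjacent bin pairs where both
    bins are non-dropout, never across a chromosome boundary.  ``mode``
    selects the mean (default) or the median of the absolute differences.
    """
    if mode not in ("mean", "median"):
        raise ValueError("mode must be 'mean' or 'median'")
    values = np.asarray(values, dtype=float)
    chrom_labels = np.asarray(chrom_labels)
    if dropout_mask is None:
        dropout_mask = ~np.isfinite(values)
    diffs = []
    same_chrom = chrom_labels[1:] == chrom_labels[:-1]
    ok = same_chrom & ~dropout_mask[1:] & ~dropout_mask[:-1]
    diffs = np.abs(values[1:] - values[:-1])[ok]
    if diffs.size == 0:
        raise ValueError("no valid adjacent bin pair")
    return float(np.mean(diffs) if mode == "mean" else np.median(diffs))


def qc_gate(
    mad: float,
    dropout: float,
    mad_threshold: float = MAD_THRESHOLD,
    dropout_threshold: float = DROPOUT_THRESHOLD,
) -> tuple[bool, list[str]]:
    """Inclusive pass/fail gate: MAD <= 1 and dropout <= 0.5 by default.

    Returns ``(passed, reasons)`` where reasons names each failed
    criterion.
    """
    reasons = []
    if mad > mad_threshold:
        reasons.append("MAD")
    if dropout > dropout_threshold:
        reasons.append("dropout")
    return (len(reasons) == 0, reasons)


def lorenz_curve(counts: BinCounts | np.ndarray) -> tuple[np.ndarray, float]:
    """Lorenz curve and Gini coefficient of per-bin read counts.

    Bins are sorted by count ascending; the curve is cumulative bin
    fraction vs cumulative read fraction, starting at (0, 0) and ending at
    (1, 1), and lies on the diagonal only for perfectly uniform counts.
    Gini = 1 - 2 x (trapezoidal area under the curve).
    """
    arr = counts.counts if isinstance(counts, BinCounts) else np.asarray(counts, float)
    if arr.size == 0 or arr.sum() <= 0:
        raise ValueError("need at least one nonzero bin count")
    srt = np.sort(np.asarray(arr, dtype=float))
    n = srt.size
    x = np.concatenate(([0.0], np.arange(1, n + 1) / n))
    y = np.concatenate(([0.0], np.cumsum(srt) / srt.sum()))
    area = np.trapezoid(y, x)
    gini = float(1.0 - 2.0 * area)
    return np.column_stack([x, y]), gini


def qc_report(
    sample_id: str,
    scaled_cn: np.ndarray,
    chrom_labels: np.ndarray,
    counts: BinCounts | np.ndarray,
    mad_mode: str = "mean",
    mad_threshold: float = MAD_THRESHOLD,
    dropout_threshold: float = DROPOUT_THRESHOLD,
    dropout_mask: np.ndarray | None = None,
) -> QCReport:
    """Assemble the full QC report for one cell."""
    from .binning import dropout_ratio

    mad = mad_adjacent(scaled_cn, chrom_labels, mode=mad_mode,
                       dropout_mask=dropout_mask)
    dropout = dropout_ratio(counts)
    passed, reasons = qc_gate(mad, dropout, mad_threshold, dropout_threshold)
    arr = counts.counts if isinstance(counts, BinCounts) else np.asarray(counts)
    if arr.sum() > 0:
        lorenz, gini = lorenz_curve(counts)
    else:
        lorenz, gini = None, None
    return QCReport(
        sample_id=sample_id, mad=mad, mad_mode=mad_mode, dropout=dropout,
        passed=passed, reasons=reasons, mad_threshold=mad_threshold,
        dropout_threshold=dropout_threshold, lorenz=lorenz, gini=gini,
    )
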