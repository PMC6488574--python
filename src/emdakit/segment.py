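"""Circular binary segmentation (CBS) with permutation significance.

Recursive changepoint detection on per-bin copy-number series: within each
current segment, the arc (i, j] maximizing the two-sample t-like statistic
between the arc and its complement is found by exhaustive search; the split
is accepted when its permutation p-value falls below ``alpha`` and the
recursion continues on the resulting pieces.  Treating the segment as a
circle lets a single pass discover events that sit in the interior (two
breakpoints at once).

The permutation test uses sequential early rejection: once the number of
permuted maxima exceeding the observed statistic reaches ``alpha x
n_permutations``, the split can no longer be significant and permutation
stops.  Accepted splits always run the full permutation budget, so the
decision is identical to the non-sequential test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SegmentSet", "cbs_segment", "max_arc_statistic"]


@dataclass
class SegmentSet:
    """Segmentation of a binned genome.

    ``segments`` columns: chrom, start_bin, end_bin (half-open indices into
    the full bin vector), n_bins, mean (mean scaled copy number over
    non-dropout member bins), integer_cn (= round half away from zero).
    """

    segments: pd.DataFrame
    alpha: float
    n_permutations: int

    def __len__(self) -> int:
        return len(self.segments)


_weight_cache: dict[int, np.ndarray] = {}


def _arc_weights(n: int) -> np.ndarray:
    """sqrt(n / (m (n-m))) for every arc (i, j], zero where the arc is
    degenerate (empty or the full series).  Cached per series length."""
    w = _weight_cache.get(n)
    if w is None:
        i = np.arange(n + 1)[:, None]
        j = np.arange(n + 1)[None, :]
        m = j - i
        valid = (m >= 1) & (m <= n - 1)
        mm = np.where(valid, m, 1)
        w = np.where(valid, np.sqrt(n / (mm * (n - mm))), 0.0)
        if len(_weight_cache) > 32:
            _weight_cache.clear()
        _weight_cache[n] = w
    return w


def max_arc_statistic(x: np.ndarray) -> tuple[float, int, int]:
    """Best circular-arc split of a series.

    Returns ``(z, i, j)`` maximizing the standardized mean-shift statistic
    between the arc ``x[i:j]`` and its complement,

        Z(i, j) = |mean_arc - mean_complement| / sqrt(1/m + 1/k),

    over all ``0 <= i < j <= n`` with both parts non-empty.  This is the
    arc statistic of circular binary segmentation up to the global noise
    scale, which is invariant under permutation and therefore cancels from
    the permutation test.  Equivalently Z = |y_j - y_i| sqrt(n/(m k)) where
    y is the cumulative-sum bridge of x.  O(n^2) time and memory.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 points")
    cs = np.concatenate(([0.0], np.cumsum(x)))
    y = cs - (cs[-1] / n) * np.arange(n + 1)
    z = np.abs(y[None, :] - y[:, None]) * _arc_weights(n)
    flat = int(np.argmax(z))
    bi, bj = divmod(flat, n + 1)
    return float(z[bi, bj]), int(bi), int(bj)


def _max_arc_value(y: np.ndarray, w: np.ndarray) -> float:
    return float(np.max(np.abs(y[None, :] - y[:, None]) * w))


def _split_significant(x, z_obs, alpha, n_perm, rng) -> bool:
    """Sequential permutation test of the best-arc statistic.

    Early-rejects once the exceedance count can no longer fall below
    ``alpha x n_perm``; accepted splits always consume the full budget, so
    the decision matches the non-sequential test exactly.
    """
    n = len(x)
    w = _arc_weights(n)
    frame = np.arange(n + 1)
    limit = int(np.ceil(alpha * n_perm))
    exceed = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        cs = np.concatenate(([0.0], np.cumsum(xp)))
        y = cs - (cs[-1] / n) * frame
        if _max_arc_value(y, w) >= z_obs:
            exceed += 1
            if exceed >= limit:
                return False
    return exceed < alpha * n_perm


def _segment_series(x, alpha, n_perm, rng) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome's series; returns half-open pieces."""
    out: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        a, b = stack.pop()
        if b - a < 2:
            out.append((a, b))
            continue
        seg = x[a:b]
        if np.ptp(seg) == 0:
            out.append((a, b))
            continue
        t, i, j = max_arc_statistic(seg)
        if t > 0 and _split_significant(seg, t, alpha, n_perm, rng):
            parts = [(a, a + i), (a + i, a + j), (a + j, b)]
            for p in parts:
                if p[1] > p[0]:
                    stack.append(p)
        else:
            out.append((a, b))
    out.sort()
    return out


def _merge_short(pieces, x, min_width):
    """Merge segments shorter than min_width into the neighbour with the
    nearest mean."""
    pieces = list(pieces)
    changed = True
    while changed and len(pieces) > 1:
        changed = False
        for k, (a, b) in enumerate(pieces):
            if b - a >= min_width:
                continue
            mean = x[a:b].mean()
            cand = []
            if k > 0:
                la, lb = pieces[k - 1]
                cand.append((abs(x[la:lb].mean() - mean), k - 1))
            if k < len(pieces) - 1:
                ra, rb = pieces[k + 1]
                cand.append((abs(x[ra:rb].mean() - mean), k + 1))
            _, tgt = min(cand)
            lo = min(pieces[k][0], pieces[tgt][0])
            hi = max(pieces[k][1], pieces[tgt][1])
            pieces[min(k, tgt)] = (lo, hi)
            del pieces[max(k, tgt)]
            changed = True
            break
    return pieces


def _round_half_away(x):
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def cbs_segment(
    scaled_cn: np.ndarray,
    chrom_labels: np.ndarray,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    seed: int = 0,
    dropout_mask: np.ndarray | None = None,
    min_segment_bins: int = 3,
    prune: bool = True,
) -> SegmentSet:
    """Segment a per-bin scaled copy-number series into constant pieces.

    Each chromosome is segmented independently on its non-dropout bins;
    segment boundaries are then mapped back to the full bin vector so the
    segments partition every bin (dropout bins inherit the enclosing
    segment but contribute nothing to its mean).  Segments shorter than
    ``min_segment_bins`` are merged into the neighbour with the nearest
    mean unless ``prune=False``.  Deterministic given ``seed``.
    """
    scaled_cn = np.asarray(scaled_cn, dtype=float)
    chrom_labels = np.asarray(chrom_labels)
    if dropout_mask is None:
        dropout_mask = np.zeros(len(scaled_cn), dtype=bool)
    rng = np.random.default_rng(seed)

    rows = []
    for chrom in dict.fromkeys(chrom_labels):
        idx = np.flatnonzero(chrom_labels == chrom)
        keep = idx[~dropout_mask[idx]]
        if len(keep) < 2:
            if len(idx):
                mean = float(scaled_cn[keep].mean()) if len(keep) else np.nan
                rows.append((chrom, idx[0], idx[-1] + 1, len(idx), mean))
            continue
        x = scaled_cn[keep]
        pieces = _segment_series(x, alpha, n_permutations, rng)
        if prune:
            pieces = _merge_short(pieces, x, min_segment_bins)
        # map boundaries on the non-dropout axis back to full bin indices
        for pk, (a, b) in enumerate(pieces):
            start = idx[0] if pk == 0 else keep[a]
            end = idx[-1] + 1 if pk == len(pieces) - 1 else keep[b - 1] + 1
            rows.append((chrom, int(start), int(end), int(end - start),
                         float(x[a:b].mean())))
    seg = pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin", "n_bins", "mean"])
    seg["integer_cn"] = _round_half_away(seg["mean"].to_numpy()).astype(int)
    return SegmentSet(segments=seg, alpha=alpha, n_permutations=n_permutations)
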