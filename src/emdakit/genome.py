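"""Synthetic reference genome and ground-truth copy-number profiles.

A :class:`GenomeModel` is a desk-scale stand-in for a real reference: a few
chromosomes of 1-100 Mb carrying per-window GC and mappability tracks and a
set of phased heterozygous sites.  A :class:`TruthProfile` is the ground-truth
integer copy-number landscape a simulated cell carries, against which the
recovered profiles are scored.

All genomic coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeModel", "TruthProfile", "make_genome", "make_truth_profile"]

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeModel:
    """Synthetic reference: chromosome sizes, GC/mappability tracks, het sites.

    Attributes
    ----------
    chromosomes:
        Ordered ``(name, length)`` pairs; lengths are multiples of ``window``.
    window:
        Track resolution in bases.
    gc:
        Per-chromosome GC fraction per window, each in [0, 1].
    mappability:
        Per-chromosome uniquely-mappable fraction per window, each in [0, 1].
    het_sites:
        DataFrame with columns ``chrom, pos, ref, alt`` — phased heterozygous
        sites; haplotype A carries ``ref``, haplotype B carries ``alt``.
        ``pos`` is 0-based.
    """

    chromosomes: list[tuple[str, int]]
    window: int
    gc: dict[str, np.ndarray]
    mappability: dict[str, np.ndarray]
    het_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt"]
        )
    )

    def __post_init__(self) -> None:
        for name, length in self.chromosomes:
            if length <= 0 or length % self.window != 0:
                raise ValueError(
                    f"chromosome {name}: length must be a positive multiple "
                    f"of the window size {self.window}"
                )
            nwin = length // self.window
            for track, label in ((self.gc, "gc"), (self.mappability, "mappability")):
                arr = np.asarray(track[name], dtype=float)
                if arr.shape != (nwin,):
                    raise ValueError(f"{label} track for {name} does not tile the chromosome")
                if arr.min() < 0 or arr.max() > 1:
                    raise ValueError(f"{label} track for {name} outside [0, 1]")
                track[name] = arr
        if len(self.het_sites):
            for chrom, grp in self.het_sites.groupby("chrom", sort=False):
                length = dict(self.chromosomes)[chrom]
                pos = grp["pos"].to_numpy()
                if pos.min() < 0 or pos.max() >= length:
                    raise ValueError(f"het site outside chromosome {chrom}")
                if not (np.diff(pos) > 0).all():
                    raise ValueError(f"het sites on {chrom} not sorted/unique")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def n_windows(self, chrom: str) -> int:
        return self.chrom_lengths[chrom] // self.window


@dataclass
class TruthProfile:
    """Ground-truth copy-number events on a genome.

    ``events`` are non-overlapping ``(chrom, start, end, cn)`` intervals in
    0-based half-open coordinates; everything else sits at ``baseline_ploidy``.
    """

    events: list[tuple[str, int, int, int]]
    baseline_ploidy: int = 2

    def __post_init__(self) -> None:
        if self.baseline_ploidy < 1:
            raise ValueError("baseline_ploidy must be >= 1")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, cn in self.events:
            if not (0 <= start < end) or cn < 0:
                raise ValueError(f"bad event {(chrom, start, end, cn)}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping events on {chrom}")

    def cn_windows(self, genome: GenomeModel) -> dict[str, np.ndarray]:
        """Integer copy number per track window, per chromosome.

        A window takes the copy number covering its start (events are
        generated window-aligned, so this is exact for simulated truth).
        """
        out = {}
        for chrom, length in genome.chromosomes:
            cn = np.full(length // genome.window, self.baseline_ploidy, dtype=int)
            for c, start, end, value in self.events:
                if c != chrom:
                    continue
                w0 = start // genome.window
                w1 = -(-end // genome.window)  # ceil
                cn[w0:w1] = value
            out[chrom] = cn
        return out

    def mean_copy_number(self, genome: GenomeModel) -> float:
        cn = self.cn_windows(genome)
        return float(np.mean(np.concatenate([cn[c] for c, _ in genome.chromosomes])))


def make_genome(
    n_chrom: int = 2,
    chrom_length: int = 10_000_000,
    window: int = 10_000,
    gc_model: dict | None = None,
    mappability_model: dict | None = None,
    n_het_sites: int = 0,
    seed: int = 0,
) -> GenomeModel:
    """Generate a reproducible synthetic genome.

    GC is a clipped AR(1) process (smooth isochore-like variation around a
    mean of 0.42, matching the mammalian genome-wide average); mappability is
    1 for most windows with a random subset depressed, mimicking repeats.

    Parameters
    ----------
    gc_model:
        ``{"mean": 0.42, "sd": 0.06, "corr": 0.9}`` — stationary mean/sd and
        the lag-one autocorrelation of the per-window GC process.
    mappability_model:
        ``{"p_low": 0.05, "low_range": (0.2, 0.8)}`` — fraction of windows
        with depressed mappability, and the uniform range they are drawn
        from.  ``p_low=0`` gives a perfectly mappable genome.
    n_het_sites:
        Total phased heterozygous sites, placed uniformly (unique, sorted)
        across the genome.
    """
    if chrom_length <= 0 or window <= 0 or chrom_length % window != 0:
        raise ValueError("chrom_length must be a positive multiple of window")
    if window > chrom_length:
        raise ValueError("window larger than chromosome")
    gc_model = {"mean": 0.42, "sd": 0.06, "corr": 0.9, **(gc_model or {})}
    mappability_model = {"p_low": 0.05, "low_range": (0.2, 0.8), **(mappability_model or {})}

    rng = np.random.default_rng(seed)
    nwin = chrom_length // window
    chromosomes = [(f"chr{i + 1}", chrom_length) for i in range(n_chrom)]
    gc, mappability = {}, {}
    for name, _ in chromosomes:
        rho, mu, sd = gc_model["corr"], gc_model["mean"], gc_model["sd"]
        innov = rng.normal(0.0, sd * np.sqrt(1 - rho**2), nwin)
        track = np.empty(nwin)
        track[0] = mu + rng.normal(0.0, sd)
        for i in range(1, nwin):
            track[i] = mu + rho * (track[i - 1] - mu) + innov[i]
        gc[name] = np.clip(track, 0.2, 0.8)

        mp = np.ones(nwin)
        low = rng.random(nwin) < mappability_model["p_low"]
        lo, hi = mappability_model["low_range"]
        mp[low] = rng.uniform(lo, hi, int(low.sum()))
        mappability[name] = mp

    het = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    if n_het_sites > 0:
        total = n_chrom * chrom_length
        flat = rng.choice(total, size=n_het_sites, replace=False)
        flat.sort()
        chrom_idx = flat // chrom_length
        pos = flat % chrom_length
        ref_i = rng.integers(0, 4, n_het_sites)
        alt_i = (ref_i + rng.integers(1, 4, n_het_sites)) % 4
        het = pd.DataFrame(
            {
                "chrom": [chromosomes[i][0] for i in chrom_idx],
                "pos": pos,
                "ref": _BASES[ref_i],
                "alt": _BASES[alt_i],
            }
        )
        het = het.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    return GenomeModel(chromosomes, window, gc, mappability, het)


def make_truth_profile(
    genome: GenomeModel,
    n_events: int = 5,
    size_range: tuple[int, int] = (1_000_000, 5_000_000),
    cn_states: tuple[int, ...] = (1, 3),
    baseline: int = 2,
    seed: int = 0,
    max_tries: int = 1000,
) -> TruthProfile:
    """Place non-overlapping copy-number events of the given sizes.

    Events are window-aligned and carry copy numbers drawn from
    ``cn_states`` (baseline excluded).  Raises if the events cannot be
    placed without overlap within ``max_tries`` rejection-sampling rounds.
    """
    states = [s for s in cn_states if s != baseline]
    if n_events > 0 and not states:
        raise ValueError("cn_states must contain a non-baseline state")
    lo, hi = size_range
    if lo > max(length for _, length in genome.chromosomes):
        raise ValueError("event size exceeds every chromosome")
    if n_events * lo > genome.total_length:
        raise ValueError("requested events cannot fit in the genome")

    rng = np.random.default_rng(seed)
    w = genome.window
    placed: list[tuple[str, int, int, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in genome.chromosomes}
    lengths = genome.chrom_lengths
    names = [c for c, _ in genome.chromosomes]
    weights = np.array([lengths[c] for c in names], dtype=float)
    weights /= weights.sum()

    tries = 0
    while len(placed) < n_events:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place non-overlapping events; genome too crowded")
        chrom = rng.choice(names, p=weights)
        size = w * max(1, int(rng.integers(lo, hi + 1) // w))
        if size >= lengths[chrom]:
            continue
        start = w * int(rng.integers(0, (lengths[chrom] - size) // w + 1))
        end = start + size
        if any(start < e and s < end for s, e in occupied[chrom]):
            continue
        cn = int(rng.choice(states))
        occupied[chrom].append((start, end))
        placed.append((chrom, start, end, cn))

    placed.sort(key=lambda ev: (names.index(ev[0]), ev[1]))
    return TruthProfile(events=placed, baseline_ploidy=baseline)
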