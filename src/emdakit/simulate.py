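"""Generative model of emulsion vs one-pot multiple displacement amplification.

The model follows the physical picture of droplet MDA.  A cell's genome is
fragmented into ~10-kb templates; each template either survives handling or
is lost; survivors are scattered at random over the droplets of the emulsion.
Every occupied droplet amplifies to reagent saturation, so the *total*
product per droplet is (nearly) fixed, while templates sharing a droplet
compete: their shares of the droplet's yield are exponentially dispersed.
With many droplets most templates sit alone and receive the full saturation
yield — amplification is even.  In a single pot (``n_droplets=1``) every
template competes with every other, reproducing the classic one-pot MDA
coverage bias.  Empty droplets still consume primers and emit
random-primer-annealing product that cannot be mapped, so over-dilution
buys evenness at the price of mapping rate.

Sequencing is modelled as a multinomial draw of reads over template product
mass plus the unmappable pool; read positions, per-window counts and
haplotype-resolved depths at heterozygous sites are tallied exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel, TruthProfile

__all__ = ["SimConfig", "SimOutput", "simulate_amplification", "simulate_bulk"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one amplification + sequencing simulation.

    Parameters
    ----------
    n_droplets:
        Number of emulsion compartments; ``1`` means one-pot (tube) MDA.
        ``None`` resolves to ``ceil(templates / 0.7)`` at run time — the
        0.4-0.7 templates-per-droplet regime of a 30-50 uL reaction of
        40-um droplets, where most droplets hold at most one template.
    fragment_length:
        Template fragment size in bases (~10 kb after routine handling).
    saturation_yield:
        Product mass per occupied droplet at reagent exhaustion (arbitrary
        units; only ratios matter).
    within_droplet_cv:
        Log-scale sd of the droplet-total yield jitter around saturation.
    tube_bias_sigma:
        Log-scale sd of per-template competition: within a droplet (or the
        single pot) template product shares are lognormal(0, sigma)
        renormalized to the droplet total.  Governs one-pot bias and the
        residual bias of overcrowded droplets.
    empty_droplet_background:
        Unmappable product mass emitted by each *empty* droplet, as a
        fraction of the saturation yield (random primer annealing).
    fragment_loss_prob:
        Probability a template fragment is lost before amplification.
    gc_bias_coefficients:
        ``(c1, c2)`` of the multiplicative amplification efficiency
        ``exp(c1 z + c2 z^2)`` with ``z = GC - 0.5`` of the fragment's
        window.
    total_reads:
        Sequencing depth in reads; mapped + unmapped reads sum to this.
    read_length:
        Read length in bases (single-end).
    seed:
        Seed for the single generator driving every stochastic step.
    """

    n_droplets: int | None = None
    fragment_length: int = 10_000
    saturation_yield: float = 1.0
    within_droplet_cv: float = 0.2
    tube_bias_sigma: float = 1.5
    empty_droplet_background: float = 0.3
    fragment_loss_prob: float = 0.05
    gc_bias_coefficients: tuple[float, float] = (0.0, 0.0)
    total_reads: int = 200_000
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets is not None and self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if not 0 <= self.fragment_loss_prob <= 1:
            raise ValueError("fragment_loss_prob must be in [0, 1]")
        if self.empty_droplet_background < 0:
            raise ValueError("empty_droplet_background must be >= 0")
        if self.total_reads <= 0 or self.fragment_length <= 0 or self.read_length <= 0:
            raise ValueError("total_reads, fragment_length, read_length must be positive")


@dataclass
class SimOutput:
    """Result of one simulated cell (or bulk sample).

    ``reads`` holds the mapped reads as BED-like records
    (chrom, start, end, mapq); ``window_counts`` tallies them at the
    genome's track resolution; ``allele_depths`` gives haplotype-resolved
    depths at the genome's het sites with 1-based ``pos`` (VCF convention);
    ``mapping_rate`` = mapped / total reads.
    """

    sample_id: str
    reads: pd.DataFrame
    window_counts: dict[str, np.ndarray]
    total_reads: int
    mapped_reads: int
    allele_depths: pd.DataFrame
    truth: TruthProfile
    lineage: pd.DataFrame | None = None

    @property
    def mapping_rate(self) -> float:
        return self.mapped_reads / self.total_reads if self.total_reads else 0.0


# ---------------------------------------------------------------------------
# fragment generation

def _template_fragments(genome, truth, frag_len, rng):
    """Tile every template copy with length-L fragments at a random phase.

    Copy number c at a locus means c template copies: copy index i carries
    haplotype A for even i, B for odd i (so diploid = one of each, CN 1 =
    haplotype A only, CN 3 = A,B,A).  Tiling guarantees each copy
    contributes exactly one fragment over any position, which makes the
    fragment-loss model analytically invertible downstream (allele dropout).
    Expected per-window fragment counts equal window/L per copy, as for
    uniform fragmentation.
    """
    cn_win = truth.cn_windows(genome)
    w = genome.window
    chroms, starts, ends, haps = [], [], [], []
    for ci, (chrom, length) in enumerate(genome.chromosomes):
        cn = cn_win[chrom]
        max_cn = int(cn.max(initial=0))
        for copy in range(max_cn):
            present = cn > copy
            if not present.any():
                continue
            # runs of consecutive windows where this copy exists
            edges = np.flatnonzero(np.diff(np.concatenate(([0], present.view(np.int8), [0]))))
            for run_start, run_end in edges.reshape(-1, 2):
                a, b = run_start * w, run_end * w
                phase = rng.integers(0, frag_len)
                fs = np.arange(a - phase, b, frag_len)
                fe = np.minimum(fs + frag_len, b)
                fs = np.maximum(fs, a)
                keep = fe > fs
                fs, fe = fs[keep], fe[keep]
                chroms.append(np.full(len(fs), ci, dtype=np.int32))
                starts.append(fs)
                ends.append(fe)
                haps.append(np.full(len(fs), copy % 2, dtype=np.int8))
    if not starts:
        empty = np.array([], dtype=np.int64)
        return empty.astype(np.int32), empty, empty, empty.astype(np.int8)
    return (
        np.concatenate(chroms),
        np.concatenate(starts),
        np.concatenate(ends),
        np.concatenate(haps),
    )


def _gc_factor(gc, coeffs):
    z = gc - 0.5
    return np.exp(coeffs[0] * z + coeffs[1] * z * z)


def _tally(genome, chrom_ids, read_starts, read_haps, read_length, sample_id, truth):
    """Per-window counts, BED-like read table, and het-site allele depths."""
    names = [c for c, _ in genome.chromosomes]
    w = genome.window
    window_counts = {c: np.zeros(genome.n_windows(c), dtype=np.int64) for c in names}
    frames = []
    het = genome.het_sites
    depth_a = np.zeros(len(het), dtype=np.int64)
    depth_b = np.zeros(len(het), dtype=np.int64)
    for ci, chrom in enumerate(names):
        sel = chrom_ids == ci
        if not sel.any():
            continue
        starts = read_starts[sel]
        haps = read_haps[sel]
        order = np.argsort(starts, kind="stable")
        starts, haps = starts[order], haps[order]
        np.add.at(window_counts[chrom], starts // w, 1)
        length = genome.chrom_lengths[chrom]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + read_length, length),
                    "mapq": 60,
                }
            )
        )
        if len(het):
            site_rows = np.flatnonzero((het["chrom"] == chrom).to_numpy())
            pos = het["pos"].to_numpy()[site_rows]
            lo = np.searchsorted(starts, pos - read_length + 1, side="left")
            hi = np.searchsorted(starts, pos, side="right")
            hap_cum = np.concatenate(([0], np.cumsum(haps)))
            n_b = hap_cum[hi] - hap_cum[lo]
            depth_b[site_rows] = n_b
            depth_a[site_rows] = (hi - lo) - n_b
    reads = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "start", "end", "mapq"])
    )
    allele_depths = pd.DataFrame(
        {
            "chrom": het["chrom"].to_numpy(),
            "pos": het["pos"].to_numpy() + 1,  # 1-based, VCF convention
            "ref": het["ref"].to_numpy(),
            "alt": het["alt"].to_numpy(),
            "ref_depth": depth_a,
            "alt_depth": depth_b,
        }
    )
    return window_counts, reads, allele_depths


def simulate_amplification(
    genome: GenomeModel,
    truth: TruthProfile,
    cfg: SimConfig,
    sample_id: str = "cell",
    keep_lineage: bool = False,
) -> SimOutput:
    """Simulate one MDA-amplified, sequenced cell.

    Pipeline: fragment the template copies, lose fragments at
    ``fragment_loss_prob``, scatter survivors over ``n_droplets``, assign
    product mass per droplet (saturation total, competing lognormal shares),
    modulate by GC efficiency and window mappability, pool unmappable mass
    from empty droplets and unmappable genome fractions, then draw
    ``total_reads`` multinomially and tally.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.fragment_length
    names = [c for c, _ in genome.chromosomes]

    chrom_ids, fstart, fend, fhap = _template_fragments(genome, truth, L, rng)
    n_frag = len(fstart)

    # fragment loss
    survived = rng.random(n_frag) >= cfg.fragment_loss_prob
    chrom_ids, fstart, fend, fhap = (
        chrom_ids[survived], fstart[survived], fend[survived], fhap[survived]
    )
    n_surv = len(fstart)

    n_droplets = cfg.n_droplets
    if n_droplets is None:
        n_droplets = max(1, int(np.ceil(n_surv / 0.7))) if n_surv else 1

    if n_surv == 0:
        warnings.warn("no template fragments survived; all counts are zero")
        window_counts = {c: np.zeros(genome.n_windows(c), dtype=np.int64) for c in names}
        _, reads, allele_depths = _tally(
            genome, np.array([], dtype=np.int32), np.array([], dtype=np.int64),
            np.array([], dtype=np.int8), cfg.read_length, sample_id, truth,
        )
        return SimOutput(sample_id, reads, window_counts, cfg.total_reads, 0,
                         allele_depths, truth)

    # droplet assignment and per-template product mass
    droplet = rng.integers(0, n_droplets, n_surv)
    occupied, group = np.unique(droplet, return_inverse=True)
    n_occupied = len(occupied)
    shares = rng.lognormal(0.0, cfg.tube_bias_sigma, n_surv)
    share_sum = np.bincount(group, weights=shares, minlength=n_occupied)
    droplet_yield = cfg.saturation_yield * rng.lognormal(
        0.0, cfg.within_droplet_cv, n_occupied
    )
    mass = droplet_yield[group] * shares / share_sum[group]
    # partial fragments at event edges carry proportionally less template
    mass *= (fend - fstart) / L

    # GC efficiency and mappability of the fragment's window
    mid_win = ((fstart + fend) // 2) // genome.window
    gc = np.empty(n_surv)
    mp = np.empty(n_surv)
    for ci, chrom in enumerate(names):
        sel = chrom_ids == ci
        gc[sel] = genome.gc[chrom][mid_win[sel]]
        mp[sel] = genome.mappability[chrom][mid_win[sel]]
    mass *= _gc_factor(gc, cfg.gc_bias_coefficients)
    mapped_mass = mass * mp

    n_empty = n_droplets - n_occupied
    unmappable = (
        n_empty * cfg.empty_droplet_background * cfg.saturation_yield
        + float((mass * (1.0 - mp)).sum())
    )

    # sequencing: multinomial over fragments + the unmappable pool
    weights = np.concatenate([mapped_mass, [unmappable]])
    total = weights.sum()
    if total <= 0:
        counts = np.zeros(n_surv + 1, dtype=np.int64)
        counts[-1] = cfg.total_reads
    else:
        counts = rng.multinomial(cfg.total_reads, weights / total)
    frag_reads = counts[:-1]
    mapped_reads = int(frag_reads.sum())

    # read starts are uniform over the whole fragment span (reads may run
    # past the tile boundary): coverage intensity stays uniform along each
    # template copy, with no dead zone at fragment ends
    rep = np.repeat(np.arange(n_surv), frag_reads)
    span = fend[rep] - fstart[rep]
    read_starts = fstart[rep] + rng.integers(0, span)
    window_counts, reads, allele_depths = _tally(
        genome, chrom_ids[rep], read_starts, fhap[rep], cfg.read_length,
        sample_id, truth,
    )

    lineage = None
    if keep_lineage:
        lineage = pd.DataFrame(
            {
                "chrom": [names[i] for i in chrom_ids],
                "start": fstart,
                "end": fend,
                "haplotype": np.where(fhap == 0, "A", "B"),
                "droplet": droplet,
                "mass": mass,
                "reads": frag_reads,
            }
        )
    return SimOutput(sample_id, reads, window_counts, cfg.total_reads,
                     mapped_reads, allele_depths, truth, lineage)


def simulate_bulk(
    genome: GenomeModel,
    truth: TruthProfile,
    total_reads: int = 500_000,
    seed: int = 0,
    read_length: int = 100,
    sample_id: str = "bulk",
) -> SimOutput:
    """Simulate an unamplified bulk sample: no amplification noise.

    Reads fall multinomially over windows with probability proportional to
    copy number x mappability; at het sites both haplotypes are present and
    depth splits according to the local haplotype composition.
    """
    rng = np.random.default_rng(seed)
    cn_win = truth.cn_windows(genome)
    names = [c for c, _ in genome.chromosomes]
    w = genome.window
    weights = np.concatenate(
        [cn_win[c] * genome.mappability[c] for c in names]
    ).astype(float)
    offsets = np.cumsum([0] + [genome.n_windows(c) for c in names])
    if weights.sum() <= 0:
        raise ValueError("genome has no mappable copied territory")
    counts = rng.multinomial(total_reads, weights / weights.sum())

    chrom_ids = np.empty(total_reads, dtype=np.int32)
    starts = np.empty(total_reads, dtype=np.int64)
    k = 0
    for ci, chrom in enumerate(names):
        c = counts[offsets[ci]:offsets[ci + 1]]
        n = int(c.sum())
        win_idx = np.repeat(np.arange(len(c)), c)
        starts[k:k + n] = win_idx * w + rng.integers(0, w, n)
        chrom_ids[k:k + n] = ci
        k += n

    # haplotype of each read: A with prob (#A copies / cn) of its window
    hap = np.zeros(total_reads, dtype=np.int8)
    for ci, chrom in enumerate(names):
        sel = chrom_ids == ci
        cn = cn_win[chrom][starts[sel] // w]
        n_a = (cn + 1) // 2  # copies alternate A,B,A,...
        p_b = np.where(cn > 0, (cn - n_a) / np.maximum(cn, 1), 0.0)
        hap[sel] = rng.random(int(sel.sum())) < p_b

    window_counts, reads, allele_depths = _tally(
        genome, chrom_ids, starts, hap, read_length, sample_id, truth
    )
    return SimOutput(sample_id, reads, window_counts, total_reads,
                     total_reads, allele_depths, truth)
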