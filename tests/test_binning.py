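"""Dynamic binning and read counting, with hand-computed toy oracles."""

import numpy as np
import pandas as pd
import pytest

import emdakit as ek
from emdakit.genome import GenomeModel


def toy_alignments(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "mapq"])
    df["end"] = df["start"] + 100
    return df[["chrom", "start", "end", "mapq"]]


def track_genome(mappability, window=10_000, gc=None):
    """One-chromosome genome from an explicit mappability track."""
    mappability = np.asarray(mappability, dtype=float)
    n = len(mappability)
    if gc is None:
        gc = np.full(n, 0.45)
    return GenomeModel(
        chromosomes=[("chr1", n * window)], window=window,
        gc={"chr1": np.asarray(gc, float)}, mappability={"chr1": mappability},
    )


class TestDynamicBins:
    def test_uniform_track_gives_equal_bins(self):
        g = track_genome(np.ones(100))  # 1 Mb fully mappable
        bs = ek.build_dynamic_bins(g, 50_000)
        assert len(bs) == 20
        spans = bs.bins["end"] - bs.bins["start"]
        assert (spans == 50_000).all()
        assert bs.bins["mappable"].to_numpy() == pytest.approx(np.full(20, 50_000.0))

    def test_half_mappable_region_doubles_span(self):
        # 3-region toy: 10 windows at 1.0, 10 at 0.5, 10 at 1.0
        g = track_genome([1.0] * 10 + [0.5] * 10 + [1.0] * 10)
        bs = ek.build_dynamic_bins(g, 60_000)  # quota = 60k * (250/300) = 50k
        expected = [(0, 50_000), (50_000, 100_000), (100_000, 200_000),
                    (200_000, 250_000), (250_000, 300_000)]
        got = list(zip(bs.bins["start"], bs.bins["end"]))
        assert got == expected
        assert bs.bins["mappable"].to_numpy() == pytest.approx(np.full(5, 50_000.0))

    def test_bin_size_scaling(self):
        g = track_genome(np.ones(1000))  # 10 Mb
        fine = ek.build_dynamic_bins(g, 50_000)
        coarse = ek.build_dynamic_bins(g, 1_000_000)
        assert abs(len(fine) - 20 * len(coarse)) <= 1

    def test_trailing_bin_kept_when_half_quota(self):
        g = track_genome(np.ones(103))  # 1.03 Mb: 30k leftover >= 25k
        bs = ek.build_dynamic_bins(g, 50_000)
        assert len(bs) == 21
        assert bs.bins["end"].iloc[-1] == 1_030_000

    def test_trailing_bin_merged_when_small(self):
        g = track_genome(np.ones(101))  # 10k leftover < 25k -> merged
        bs = ek.build_dynamic_bins(g, 50_000)
        assert len(bs) == 20
        assert bs.bins["end"].iloc[-1] == 1_010_000
        assert bs.bins["mappable"].iloc[-1] == pytest.approx(60_000.0)

    def test_mappable_content_conserved(self, small_genome):
        bs = ek.build_dynamic_bins(small_genome, 50_000)
        total = sum(small_genome.mappability[c].sum() * small_genome.window
                    for c, _ in small_genome.chromosomes)
        assert bs.bins["mappable"].sum() == pytest.approx(total)

    def test_deterministic(self, small_genome):
        a = ek.build_dynamic_bins(small_genome, 50_000)
        b = ek.build_dynamic_bins(small_genome, 50_000)
        pd.testing.assert_frame_equal(a.bins, b.bins)

    def test_gc_is_mappability_weighted(self):
        gc = [0.3] * 5 + [0.7] * 5
        mp = [1.0] * 5 + [0.5] * 5
        g = track_genome(mp, gc=gc)
        bs = ek.build_dynamic_bins(g, 100_000)  # quota = 75k: one full bin + rest
        # first bin: 5 windows at gc .3 weight 1 + windows at .7 weight .5
        w = bs.bins.iloc[0]
        assert 0.3 < w["gc"] < 0.7

    def test_zero_mappable_chromosome_warns(self):
        g = GenomeModel(
            chromosomes=[("chr1", 100_000), ("chr2", 100_000)], window=10_000,
            gc={"chr1": np.full(10, 0.4), "chr2": np.full(10, 0.4)},
            mappability={"chr1": np.ones(10), "chr2": np.zeros(10)},
        )
        with pytest.warns(UserWarning):
            bs = ek.build_dynamic_bins(g, 50_000)
        assert set(bs.bins["chrom"]) == {"chr1"}


class TestCountReads:
    def test_empty_alignments(self, small_binset):
        counts = ek.count_reads(small_binset, toy_alignments([]))
        assert (counts.counts == 0).all()

    def test_conservation_in_one_bin(self, small_binset):
        b3 = small_binset.bins.iloc[3]
        rows = [(b3["chrom"], int(b3["start"]) + 10, 60)] * 10
        counts = ek.count_reads(small_binset, toy_alignments(rows))
        assert counts.counts[3] == 10
        assert counts.counts.sum() == 10

    def test_mapq_filter_matches_bruteforce(self, small_binset):
        rows = [("chr1", 1000 * i, mq) for i, mq in enumerate(range(5, 85, 10))]
        aln = toy_alignments(rows)
        counts = ek.count_reads(small_binset, aln, mapq_min=15)
        expected = (aln["mapq"] >= 15).sum()
        assert counts.counts.sum() == expected
        assert counts.mapped_reads == expected

    def test_order_invariance(self, small_binset, emda_sim):
        aln = emda_sim.reads
        shuffled = aln.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = ek.count_reads(small_binset, aln)
        b = ek.count_reads(small_binset, shuffled)
        assert np.array_equal(a.counts, b.counts)

    def test_unknown_chromosome_skipped(self, small_binset):
        rows = [("chrUn", 100, 60), ("chr1", 100, 60)]
        counts = ek.count_reads(small_binset, toy_alignments(rows))
        assert counts.n_skipped == 1
        assert counts.counts.sum() == 1

    def test_midpoint_assignment(self, small_binset):
        # read starting just before a boundary, midpoint after it
        b1 = small_binset.bins.iloc[1]
        rows = [(b1["chrom"], int(b1["start"]) - 20, 60)]
        by_start = ek.count_reads(small_binset, toy_alignments(rows), by="start")
        by_mid = ek.count_reads(small_binset, toy_alignments(rows), by="midpoint")
        assert by_start.counts[0] == 1 and by_start.counts[1] == 0
        assert by_mid.counts[0] == 0 and by_mid.counts[1] == 1


class TestDropout:
    def test_examples(self):
        assert ek.dropout_ratio(np.array([1, 5, 3, 7])) == 0.0
        assert ek.dropout_ratio(np.array([0, 5, 0, 7])) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ek.dropout_ratio(np.array([]))

    def test_high_loss_shallow_cell_mostly_dropout(self, small_genome, small_binset,
                                                   flat_truth):
        cfg = ek.SimConfig(fragment_loss_prob=0.99, total_reads=500, seed=3)
        sim = ek.simulate_amplification(small_genome, flat_truth, cfg)
        counts = ek.count_reads(small_binset, sim.reads, total_reads=sim.total_reads)
        assert ek.dropout_ratio(counts) > 0.8
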