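"""Heterozygous-site calling, allele drop-out and coverage breadth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import emdakit as ek
from emdakit.snv import BULK_THRESHOLDS, SINGLE_CELL_THRESHOLDS, HetThresholds


def table(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "ref_depth", "alt_depth"]
    )


class TestCallHetSites:
    def test_thresholds_separate_cell_and_bulk(self):
        t = table([("chr1", 100, "A", "G", 27, 3)])  # depth 30, MAF 10%
        assert len(ek.call_het_sites(t, SINGLE_CELL_THRESHOLDS)) == 1
        assert len(ek.call_het_sites(t, BULK_THRESHOLDS)) == 0

    def test_depth_gate(self):
        t = table([("chr1", 100, "A", "G", 4, 4)])  # depth 8, MAF 50%
        assert len(ek.call_het_sites(t, SINGLE_CELL_THRESHOLDS)) == 1
        assert len(ek.call_het_sites(t, BULK_THRESHOLDS)) == 0

    def test_homozygous_never_called(self):
        t = table([("chr1", 100, "A", "G", 100, 0)])
        assert len(ek.call_het_sites(t, SINGLE_CELL_THRESHOLDS)) == 0

    def test_thresholds_inclusive(self):
        # MAF exactly 5% at depth exactly 5 qualifies... 1/20 = 5% at depth 20
        t = table([("chr1", 1, "A", "G", 19, 1), ("chr1", 2, "A", "G", 3, 2)])
        het = ek.call_het_sites(t, SINGLE_CELL_THRESHOLDS)
        assert het["pos"].tolist() == [1, 2]

    @given(st.integers(0, 2**31 - 1))
    def test_bulk_calls_nested_in_single_cell_calls(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        t = table([
            ("chr1", i + 1, "A", "G", int(rng.integers(0, 60)),
             int(rng.integers(0, 60)))
            for i in range(n)
        ])
        bulk = set(map(tuple, ek.call_het_sites(t, BULK_THRESHOLDS)[["chrom", "pos"]].to_numpy()))
        cell = set(map(tuple, ek.call_het_sites(t, SINGLE_CELL_THRESHOLDS)[["chrom", "pos"]].to_numpy()))
        assert bulk <= cell

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            HetThresholds(maf_min=0.6, depth_min=5)
        with pytest.raises(ValueError):
            HetThresholds(maf_min=0.05, depth_min=0)


class TestAdoRate:
    def bulk10(self):
        return {("chr1", p) for p in range(1, 11)}

    def test_no_dropout_when_both_alleles_everywhere(self):
        cell = table([("chr1", p, "A", "G", 10, 10) for p in range(1, 11)])
        rep = ek.ado_rate(cell, self.bulk10(), depth_cutoff=5)
        assert rep.ado_rate == 0.0
        assert rep.n_covered == 10

    def test_two_of_ten_single_allele(self):
        rows = [("chr1", p, "A", "G", 10, 10) for p in range(1, 9)]
        rows += [("chr1", 9, "A", "G", 20, 0), ("chr1", 10, "A", "G", 0, 20)]
        rep = ek.ado_rate(table(rows), self.bulk10(), depth_cutoff=5)
        assert rep.ado_rate == pytest.approx(0.2)
        assert rep.n_both_alleles == 8

    def test_sites_outside_bulk_ignored(self):
        rows = [("chr1", p, "A", "G", 10, 10) for p in range(1, 11)]
        rows += [("chr2", 5, "A", "G", 30, 0)]  # not a bulk het site
        rep = ek.ado_rate(table(rows), self.bulk10(), depth_cutoff=5)
        assert rep.ado_rate == 0.0

    def test_absent_sites_count_depth_zero(self):
        cell = table([("chr1", 1, "A", "G", 10, 10)])
        rep = ek.ado_rate(cell, self.bulk10(), depth_cutoff=5,
                          depth_cutoffs=[0])
        row0 = rep.by_cutoff.set_index("depth_cutoff").loc[0]
        assert row0["n_covered"] == 1  # sites missing from the table are depth 0

    def test_cutoff_ladder_reported(self):
        cell = table([("chr1", p, "A", "G", p, p) for p in range(1, 11)])
        rep = ek.ado_rate(cell, self.bulk10(), depth_cutoff=2,
                          depth_cutoffs=[2, 10, 16])
        b = rep.by_cutoff.set_index("depth_cutoff")
        assert (np.diff(b["breadth"]) <= 0).all()

    def test_zero_covered_rejected(self):
        cell = table([("chr1", 1, "A", "G", 1, 0)])
        with pytest.raises(ValueError):
            ek.ado_rate(cell, self.bulk10(), depth_cutoff=50)

    def test_region_mask_restricts_sites(self):
        rows = [("chr1", p, "A", "G", 10, 10) for p in range(1, 9)]
        rows += [("chr1", 9, "A", "G", 20, 0), ("chr1", 10, "A", "G", 0, 20)]
        # diploid mask covering only the clean sites (0-based half-open)
        rep = ek.ado_rate(table(rows), self.bulk10(), depth_cutoff=5,
                          region_mask=[("chr1", 0, 8)])
        assert rep.n_bulk_het == 8
        assert rep.ado_rate == 0.0

    def test_alt_evidence_min(self):
        cell = table([("chr1", 1, "A", "G", 19, 1)])
        lenient = ek.ado_rate(cell, {("chr1", 1)}, depth_cutoff=5,
                              alt_evidence_min=1)
        strict = ek.ado_rate(cell, {("chr1", 1)}, depth_cutoff=5,
                             alt_evidence_min=2)
        assert lenient.ado_rate == 0.0
        assert strict.ado_rate == 1.0


class TestCoverageBreadth:
    def test_direct_count(self):
        cell = table([
            ("chr1", 1, "A", "G", 0, 0), ("chr1", 2, "A", "G", 5, 0),
            ("chr1", 3, "A", "G", 30, 0), ("chr1", 4, "A", "G", 50, 50),
        ])
        targets = {("chr1", p) for p in (1, 2, 3, 4)}
        b = ek.coverage_breadth(cell, targets, depth_cutoffs=[1, 10])
        got = b.set_index("depth_cutoff")["breadth"]
        assert got.loc[1] == pytest.approx(0.75)
        assert got.loc[10] == pytest.approx(0.5)

    def test_cutoff_zero_is_full_breadth(self):
        cell = table([("chr1", 1, "A", "G", 0, 0)])
        b = ek.coverage_breadth(cell, {("chr1", 1)}, depth_cutoffs=[0])
        assert b["breadth"].iloc[0] == 1.0

    @given(st.integers(0, 2**31 - 1))
    def test_breadth_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        cell = table([
            ("chr1", i + 1, "A", "G", int(rng.integers(0, 40)), 0)
            for i in range(30)
        ])
        targets = {("chr1", i + 1) for i in range(30)}
        b = ek.coverage_breadth(cell, targets, depth_cutoffs=[0, 1, 5, 10, 20])
        assert (np.diff(b["breadth"]) <= 0).all()

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            ek.coverage_breadth(table([]), set())


class TestSimulatorIntegration:
    def test_zero_loss_isolated_channel_has_no_dropout(self):
        # competition off + uniform mappability: dropout only via fragment loss
        g = ek.make_genome(n_chrom=1, chrom_length=3_000_000, window=10_000,
                           n_het_sites=600,
                           mappability_model={"p_low": 0.0}, seed=31)
        truth = ek.TruthProfile([], baseline_ploidy=2)
        bulk = ek.simulate_bulk(g, truth, total_reads=1_500_000, seed=32)
        bulk_het = ek.call_het_sites(bulk.allele_depths, BULK_THRESHOLDS)
        cfg = ek.SimConfig(n_droplets=1, fragment_length=5_000,
                           fragment_loss_prob=0.0, tube_bias_sigma=0.0,
                           within_droplet_cv=0.0, total_reads=2_000_000, seed=33)
        sim = ek.simulate_amplification(g, truth, cfg)
        rep = ek.ado_rate(sim.allele_depths, bulk_het, depth_cutoff=8)
        assert rep.ado_rate == 0.0
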