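"""GC correction, absolute ploidy search, rounding, detection scoring."""

import numpy as np
import pandas as pd
import pytest

import emdakit as ek
from emdakit.binning import BinSet
from emdakit.cnv import integer_profile
from emdakit.segment import SegmentSet


def synthetic_binset(n_bins, gc=None, chrom="chr1", size=50_000):
    starts = np.arange(n_bins) * size
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + size,
            "mappable": float(size),
            "gc": gc if gc is not None else np.full(n_bins, 0.45),
        }
    )
    return BinSet(bins=bins, target_bin_size=size)


class TestGcCorrect:
    def test_near_identity_without_bias(self):
        rng = np.random.default_rng(0)
        n = 10_000
        gc = rng.uniform(0.3, 0.6, n)
        counts = rng.poisson(500, n).astype(float)
        bs = synthetic_binset(n, gc=gc)
        ratio, _ = ek.gc_correct(counts, bs, span=0.3)
        plain = counts / counts.mean()
        rel = np.abs(ratio - plain) / plain
        assert rel.max() < 0.02

    def test_removes_injected_smooth_bias(self):
        # deterministic counts = g(GC) for smooth quadratic g, flat truth
        rng = np.random.default_rng(1)
        n = 2000
        gc = rng.uniform(0.3, 0.6, n)
        z = gc - 0.45
        counts = 500.0 * np.exp(1.5 * z - 20.0 * z**2)
        bs = synthetic_binset(n, gc=gc)
        ratio, diag = ek.gc_correct(counts, bs, span=0.3)
        sd_before = np.std(counts / counts.mean())
        sd_after = np.std(ratio)
        assert sd_before / sd_after >= 5.0
        assert ratio.mean() == pytest.approx(1.0, abs=1e-9)
        assert {"gc", "count", "fitted"} <= set(diag.columns)

    def test_dropout_bins_excluded_and_zero(self):
        rng = np.random.default_rng(2)
        n = 500
        counts = rng.poisson(200, n).astype(float)
        counts[::25] = 0
        bs = synthetic_binset(n, gc=rng.uniform(0.35, 0.55, n))
        ratio, _ = ek.gc_correct(counts, bs)
        assert (ratio[::25] == 0).all()
        nz = ratio[counts > 0]
        assert nz.mean() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_bins_rejected(self):
        bs = synthetic_binset(8)
        with pytest.raises(ValueError):
            ek.gc_correct(np.full(8, 100.0), bs)

    def test_rank_preserved_within_gc_strata(self):
        rng = np.random.default_rng(3)
        n = 3000
        gc = rng.uniform(0.3, 0.6, n)
        counts = rng.poisson(300, n).astype(float) * np.exp(2 * (gc - 0.45))
        bs = synthetic_binset(n, gc=gc)
        ratio, _ = ek.gc_correct(counts, bs)
        stratum = (gc > 0.44) & (gc < 0.4405)
        if stratum.sum() >= 3:
            a = np.argsort(counts[stratum])
            b = np.argsort(ratio[stratum])
            assert np.array_equal(a, b)


class TestAcdPloidy:
    def test_exact_mixed_profile_ties_to_smallest(self):
        # half CN2 / half CN3 at true ploidy 2.5: residual 0 at 2.5 and 5.0
        ratio = np.array([2 / 2.5] * 150 + [3 / 2.5] * 150)
        ploidy, curve = ek.acd_ploidy(ratio)
        assert ploidy == 2.5
        r = curve.set_index("ploidy")["residual"]
        assert r.loc[2.5] == pytest.approx(0.0, abs=1e-9)
        assert r.loc[5.0] == pytest.approx(0.0, abs=1e-9)

    def test_flat_profile_returns_smallest_integer(self):
        ploidy, _ = ek.acd_ploidy(np.ones(200))
        assert ploidy == 2.0  # first integer candidate on the 1.5-6.0 grid

    def test_bin_order_irrelevant(self):
        rng = np.random.default_rng(4)
        ratio = rng.uniform(0.5, 1.5, 300)
        ratio /= ratio.mean()
        _, a = ek.acd_ploidy(ratio)
        _, b = ek.acd_ploidy(rng.permutation(ratio))
        assert np.allclose(a["residual"], b["residual"])

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            ek.acd_ploidy(np.ones(10), grid=(0.5, 6.0, 0.05))
        with pytest.raises(ValueError):
            ek.acd_ploidy(np.ones(10), grid=(2.0, 6.0, -0.1))


class TestIntegerProfile:
    def make_segments(self, means):
        rows = []
        start = 0
        for m in means:
            rows.append(("chr1", start, start + 10, 10, m))
            start += 10
        seg = pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin",
                                          "n_bins", "mean"])
        seg["integer_cn"] = 0
        return SegmentSet(segments=seg, alpha=0.01, n_permutations=100)

    def test_rounding_contract(self):
        seg = self.make_segments([2.49, 2.51, 2.5])
        out = integer_profile(seg, 30)
        assert (out[:10] == 2).all()
        assert (out[10:20] == 3).all()
        assert (out[20:] == 3).all()  # halves round away from zero

    def test_dropout_flagged_missing(self):
        seg = self.make_segments([2.0])
        mask = np.zeros(10, bool)
        mask[4] = True
        out = integer_profile(seg, 10, dropout_mask=mask)
        assert np.isnan(out[4]) and out[0] == 2

    def test_per_bin_path(self):
        seg = self.make_segments([2.0])
        out = integer_profile(seg, 10, per_bin=True,
                              scaled_cn=np.array([1.2, 2.6] * 5))
        assert out.tolist() == [1, 3] * 5


class TestDetectionRate:
    def test_sixty_of_sixtyone(self):
        # 61 reference events of 4 bins; the cell recovers all but one
        n_bins = 61 * 8
        bs = synthetic_binset(n_bins)
        events = []
        cell = np.full(n_bins, 2.0)
        for k in range(61):
            b0 = k * 8 + 2
            events.append(("chr1", b0 * 50_000, (b0 + 4) * 50_000, 3))
            if k > 0:
                cell[b0:b0 + 4] = 3
        rate = ek.detection_rate(cell, events, bs)
        assert rate == pytest.approx(60 / 61)
        assert round(100 * rate, 1) == 98.4

    def test_identity_and_baseline(self, small_binset, small_truth):
        # identical profile detects everything; flat profile detects nothing
        assert ek.detection_rate(truth_like(small_truth, small_binset), small_truth,
                                 small_binset) == 1.0
        flat = np.full(len(small_binset), 2.0)
        assert ek.detection_rate(flat, small_truth, small_binset) == 0.0

    def test_min_overlap_threshold(self):
        bs = synthetic_binset(20)
        events = [("chr1", 0, 10 * 50_000, 3)]
        cell = np.full(20, 2.0)
        cell[:5] = 3  # exactly half of the event's bins
        assert ek.detection_rate(cell, events, bs, min_overlap=0.5) == 1.0
        assert ek.detection_rate(cell, events, bs, min_overlap=0.6) == 0.0

    def test_no_events_rejected(self):
        bs = synthetic_binset(10)
        with pytest.raises(ValueError):
            ek.detection_rate(np.full(10, 2.0), [], bs)


def truth_like(truth, binset):
    """Per-bin integer profile that matches the truth exactly."""
    mid = (binset.bins["start"].to_numpy() + binset.bins["end"].to_numpy()) // 2
    cn = np.full(len(binset), float(truth.baseline_ploidy))
    for chrom, s, e, value in truth.events:
        m = (binset.chrom_labels == chrom) & (mid >= s) & (mid < e)
        cn[m] = value
    return cn


class TestEndToEnd:
    def test_noiseless_cell_recovers_truth_exactly(self, uniform_genome):
        truth = ek.TruthProfile(
            [("chr1", 300_000, 800_000, 3), ("chr1", 1_200_000, 1_600_000, 1)]
        )
        # one pot with zero bias: per-template mass is exactly equal, so the
        # only variation left is multinomial read sampling
        cfg = ek.SimConfig(
            n_droplets=1, tube_bias_sigma=0.0, within_droplet_cv=0.0,
            fragment_loss_prob=0.0, empty_droplet_background=0.0,
            total_reads=200_000, seed=5,
        )
        sim = ek.simulate_amplification(uniform_genome, truth, cfg)
        res = ek.analyze_cell(uniform_genome, sim, cbs_nperm=300, seed=1)
        expected = truth_like(truth, res.binset)
        # true mean copy number of this profile is 2.05
        assert res.profile.ploidy == pytest.approx(truth.mean_copy_number(uniform_genome), abs=0.051)
        assert np.array_equal(res.profile.integer_cn, expected)
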