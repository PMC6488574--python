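"""One simulated emulsion-MDA cell through the whole copy-number chain.

Generates a 2 x 8 Mb synthetic genome with two ground-truth CNV events,
amplifies and sequences one cell in silico (~0.1x shallow WGS), then bins,
GC-corrects, determines the absolute ploidy, segments with CBS and scores
the recovered integer profile against the truth.
"""

import emdakit as ek

genome = ek.make_genome(n_chrom=2, chrom_length=8_000_000, window=10_000, seed=1)
truth = ek.TruthProfile(
    [("chr1", 2_000_000, 4_000_000, 3), ("chr2", 1_000_000, 2_500_000, 1)],
    baseline_ploidy=2,
)
cfg = ek.SimConfig(total_reads=40_000, seed=2)  # n_droplets=None -> lambda 0.7
sim = ek.simulate_amplification(genome, truth, cfg)
res = ek.analyze_cell(genome, sim, cbs_nperm=500, seed=3)

print(f"mapping rate      {sim.mapping_rate:.3f}")
print(f"ploidy (ACD)      {res.profile.ploidy:.2f}   (truth mean CN "
      f"{truth.mean_copy_number(genome):.2f})")
print(f"MAD               {res.qc.mad:.3f}")
print(f"dropout ratio     {res.qc.dropout:.3f}")
print(f"QC verdict        {'PASS' if res.qc.passed else 'FAIL'}")
print(f"CNV detection     {res.detection:.2f}  (fraction of truth events recovered)")
print("\nsegments (bin coordinates, mean scaled CN, integer CN):")
print(res.profile.segments.segments.to_string(index=False))
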