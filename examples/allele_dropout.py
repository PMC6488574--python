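"""Allele drop-out quantified against an unamplified bulk control.

Simulates deep sequencing (~40-50x) of a diploid genome: heterozygous
sites are called in the bulk sample (MAF >= 20%, depth >= 30), then a
single amplified cell with a known fragment-loss probability is scored at
those sites.  A covered site drops out when one allele has no supporting
reads.  Under the loss model, ADO = 2p/(1+p), so the measured rate inverts
back to the loss probability p.
"""

import emdakit as ek

genome = ek.make_genome(n_chrom=1, chrom_length=5_000_000, window=10_000,
                        n_het_sites=1500,
                        mappability_model={"p_low": 0.0}, seed=21)
truth = ek.TruthProfile([], baseline_ploidy=2)

bulk = ek.simulate_bulk(genome, truth, total_reads=2_400_000, seed=5)
bulk_het = ek.call_het_sites(bulk.allele_depths, ek.BULK_THRESHOLDS)
print(f"bulk heterozygous sites: {len(bulk_het)} of 1500 simulated")

loss = 0.111  # the loss probability whose predicted ADO is 20%
cfg = ek.SimConfig(n_droplets=1, fragment_length=5_000, fragment_loss_prob=loss,
                   tube_bias_sigma=0.0, within_droplet_cv=0.0,
                   total_reads=2_000_000, seed=6)
cell = ek.simulate_amplification(genome, truth, cfg)
report = ek.ado_rate(cell.allele_depths, bulk_het, depth_cutoff=8,
                     depth_cutoffs=[1, 4, 8, 16])

print(f"\ncovered sites (depth >= 8): {report.n_covered}")
print(f"measured ADO rate:          {report.ado_rate:.3f}")
print(f"predicted 2p/(1+p):         {2 * loss / (1 + loss):.3f}")
print(f"loss recovered ado/(2-ado): {report.ado_rate / (2 - report.ado_rate):.3f}"
      f"   (simulated p = {loss})")
print("\nADO and coverage breadth across depth cutoffs:")
print(report.by_cutoff.to_string(index=False))
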