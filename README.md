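# emdakit

Single-cell copy-number and SNV analysis for emulsion whole-genome
amplification, plus a generative simulator that makes the whole chain
testable without sequencing data.

## The problem

Single-cell whole-genome sequencing needs whole-genome amplification (WGA)
first, and the standard chemistry — multiple displacement amplification
(MDA) with phi-29 polymerase — amplifies unevenly when run in one pot:
templates that get a head start grow exponentially at the expense of the
rest, burying copy-number signal under coverage bias. Compartmentalizing
the reaction into ~10⁶ picoliter water-in-oil droplets (emulsion MDA, eMDA)
fixes this: with ~0.5 templates per droplet, each template amplifies alone
to reagent saturation, so per-template gain is nearly equal.

`emdakit` implements the computational side of this workflow for people
who analyse (or design) such experiments:

- **droplets** — emulsion design arithmetic: droplet volume/count,
  templates per droplet λ = (G/L)/N<sub>droplets</sub>, Poisson occupancy
  P(K=k) = e<sup>−λ</sup>λ<sup>k</sup>/k!.
- **simulate** — a generative model of eMDA vs one-pot (tube) MDA:
  fragment tiling of every template copy, fragment loss, droplet
  assignment, saturation yield with within-droplet competition
  (lognormal shares), GC-efficiency modulation, unmappable background from
  empty droplets, multinomial read sampling, haplotype-resolved allele
  depths — all with ground truth attached.
- **binning** — dynamic bins of equal uniquely-mappable content
  (50-kb default) and per-bin read counting (MAPQ-gated).
- **cnv** — LOWESS GC correction; absolute copy-number determination (ACD)
  by grid search minimizing R(P) = Σ<sub>b</sub>(P·r<sub>b</sub> −
  round(P·r<sub>b</sub>))²; circular binary segmentation (CBS) with a
  permutation test; integer profiles; CNV detection-rate scoring.
- **qc** — adjacent-bin MAD (robust to aneuploidy: differences never cross
  chromosome boundaries), dropout ratio, the MAD ≤ 1 ∧ dropout ≤ 0.5 gate,
  Lorenz curves and Gini coefficients of coverage.
- **snv** — heterozygous-site calling from allele-depth tables
  (MAF ≥ 5 %, depth ≥ 5 for cells; MAF ≥ 20 %, depth ≥ 30 for bulk),
  allele drop-out (ADO) against bulk-called het sites, coverage breadth.

Inputs are plain formats: BED-like alignment records or per-bin count TSVs
for CNV work, VCF (AD field) or TSV allele-depth tables for SNV work.
No sequencing data is required to use — or test — any stage: the simulator
generates realistic inputs with known truth.

## Worked example

One simulated eMDA cell through the whole chain
(`examples/simulate_and_call.py`):

```python
import emdakit as ek

genome = ek.make_genome(n_chrom=2, chrom_length=8_000_000, window=10_000, seed=1)
truth = ek.TruthProfile(
    [("chr1", 2_000_000, 4_000_000, 3), ("chr2", 1_000_000, 2_500_000, 1)],
    baseline_ploidy=2,
)
sim = ek.simulate_amplification(genome, truth, ek.SimConfig(total_reads=40_000, seed=2))
res = ek.analyze_cell(genome, sim, cbs_nperm=500, seed=3)
```

prints

```
mapping rate      0.749
ploidy (ACD)      2.05   (truth mean CN 2.03)
MAD               0.443
dropout ratio     0.000
QC verdict        PASS
CNV detection     1.00  (fraction of truth events recovered)
```

The mapping rate is below 1 because empty droplets emit unmappable
random-primer product; the MAD of ~0.44 is typical for a simulated eMDA
cell at this shallow depth (a one-pot cell on the same truth comes out
around 1.5–3 and fails QC — run `examples/emulsion_vs_onepot.py`); the
ACD grid search recovers the profile's true mean copy number to the grid
step; and both ground-truth CNVs are recovered after CBS and rounding.

The other `examples/` scripts each exercise one capability: droplet
occupancy arithmetic, the emulsion-vs-one-pot comparison, the
droplet-number sweep (U-shaped MAD, falling mapping rate), and allele
drop-out measured against a bulk control and inverted back to the
simulator's fragment-loss probability.

A thin CLI mirrors the stages for shell use:

```bash
emdakit droplets --volume-ul 30
emdakit run --outdir out/ --seed 1 --n-cells 3
emdakit cnv --counts out/cell00.counts.tsv --bins out/bins.bed --outdir cnv/
emdakit qc  --profile cnv/cell00.profile.tsv --counts out/cell00.counts.tsv --out qc.json
emdakit snv --cell cell.vcf --bulk bulk.vcf --out ado.json
```

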