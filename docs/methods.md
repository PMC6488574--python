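# Methods

This note documents the models and numerical choices behind `emdakit`: what
the simulator does and does not emulate, how each analysis stage is defined,
the defaults and why, and the known limitations.

## Droplet arithmetic

Droplets are treated as spheres: V = (π/6)d³, so a 40-µm droplet holds
33.51 pL and a V-µL reaction disperses into V·10⁶/33.51 droplets
(8.95×10⁵ at 30 µL, 1.49×10⁶ at 50 µL). Droplet and fragment counts are
kept real-valued — they feed rates, never allocations. The template count
of a diploid human cell defaults to G/L with G = 6 Gb (≈6 pg of DNA) and
L = 10 kb, counting double-stranded fragments; a flag switches to
single-strand counting, which doubles the count. The double-stranded
convention reproduces the 0.4–0.7 templates-per-droplet window across
30–50 µL that motivates the emulsion design; the mean occupancy λ feeds a
Poisson law for P(empty), P(k ≤ 1) and the multi-template tail.

Measured droplet diameters in real emulsions vary by a few percent
(~39–41 µm); with the cubic dependence of volume on diameter, printed
droplet counts for nominal 40-µm emulsions can sit ~10 % above the exact
40-µm arithmetic (1.19×10⁶ at 40 µL computed here). We do not force
agreement; the computed value is reported.

## The amplification simulator

The simulator is mechanism-level, not sequence-level. It emulates, per
cell:

1. **Templates.** Every copy of every locus (per the ground-truth profile;
   copies alternate haplotypes A,B,A,…) is tiled into L-length fragments at
   a random phase, so each position is covered by exactly one fragment per
   copy. Expected per-window fragment counts equal window/L per copy, as
   for uniform fragmentation, but the loss model stays analytically
   invertible: a haplotype is absent at a site exactly when its covering
   fragment was lost. (A Poisson fragment count per window would instead
   leave a haplotype uncovered with probability e⁻¹ even with no loss.)
2. **Loss.** Each fragment is lost independently with probability
   `fragment_loss_prob` (default 0.05) — lysis, handling and capture
   losses pooled into one number.
3. **Compartments and saturation.** Surviving fragments are scattered
   uniformly over `n_droplets` compartments (`None` resolves to
   templates/0.7, the 30–50 µL design point; `1` is one-pot MDA). Every
   occupied droplet produces a fixed saturation yield Y (times a lognormal
   jitter, sd `within_droplet_cv` = 0.2); templates sharing a droplet
   *compete*: their shares of Y are lognormal(0, `tube_bias_sigma`)
   renormalized to the droplet total, with σ = 1.5 by default. One
   parameter therefore governs both the one-pot exponential bias (all
   templates in one compartment) and the residual bias of overcrowded
   droplets; a droplet with a single template gets the full yield
   regardless — the saturation-equalization mechanism that makes eMDA
   even. A literal "equal split Y/k per template" model was rejected
   because per-template masses then *concentrate* as occupancy grows,
   making low droplet counts the most even — the opposite of the
   compartment-number trade-off this simulator exists to reproduce.
4. **Unmappable background.** Each *empty* droplet emits
   `empty_droplet_background` × Y (default 0.3) of product that cannot be
   mapped (random primer annealing); mass from poorly mappable windows
   joins the same pool. The 0.3 is a free parameter chosen so the mapping
   rate falls convincingly across an over-dilution sweep; no quantitative
   yield of primer-derived product is modelled.
5. **GC bias.** Per-fragment mass is modulated by exp(c₁z + c₂z²),
   z = GC − 0.5, with the fragment's 10-kb window GC. Default (0, 0);
   the GC-correction tests inject known coefficients.
6. **Sequencing.** `total_reads` are drawn multinomially over
   {fragments} ∪ {unmappable pool} proportional to mass; mapped + unmapped
   = total exactly. Read starts are uniform over the whole fragment span
   (reads may run past a tile boundary), which keeps coverage intensity
   uniform along each copy with no dead zone at fragment ends. Per-window
   counts, BED-like read records (MAPQ 60) and haplotype-resolved depths
   at the genome's het sites are tallied exactly.

The bulk simulator skips amplification entirely: reads fall over windows
∝ copy number × mappability, and both haplotypes are always present.

**What is not emulated:** real genome sequence (synthetic GC/mappability
tracks stand in for hg19/GRCh38 tracks), read-level errors and chimeras,
polymerase fidelity, library-preparation and enrichment bias, duplicate
reads, and diploid-genome phasing structure beyond alternating copies.
Passing tests therefore demonstrate that the *analysis chain* recovers
what this mechanism generates at desk scale; they do not validate the
chemistry itself.

**Scale.** Experiments run on synthetic genomes of 2–64 Mb (windows
10 kb), 40k–80k reads per cell for shallow-WGS work — chosen to match the
~0.1× coverage regime (tens of reads per 50-kb bin) in which single-cell
CNV screening operates — and ~2–2.4M reads for deep allele-depth work
(~40–50× at sites). Cohort checks use ten seeds.

## Copy-number chain

**Dynamic binning.** Bins accumulate 10-kb windows until their uniquely
mappable content reaches quota = target_size × genome-wide mean
mappability, so bins carry equal expected counts under uniform coverage
and stretch through repeat-rich territory. Per-bin GC is the
mappability-weighted window mean. A chromosome's trailing bin is kept if
it holds ≥ 50 % of quota, else merged left. Bin files for real genomes can
be supplied as BED instead. Reads are assigned by start coordinate
(midpoint optional), gated at MAPQ ≥ 15 — the operationalization of
"uniquely mapped". Duplicates are not collapsed at the counting stage.

**GC correction.** LOWESS of count vs GC over non-dropout bins
(span 0.3); correction divides by the fit — a multiplicative bias model —
then renormalizes to mean 1. Dropout bins (count 0) are excluded from the
fit and carry corrected value 0. The pre-correction trend is returned for
QC plotting. A flat GC track short-circuits to the plain mean. Fewer than
10 usable bins is an error.

**ACD (absolute copy-number determination).** For candidate ploidies P on
a grid (default 1.5–6.0, step 0.05) the residual R(P) = Σ(P·r_b −
round(P·r_b))² is minimized; ties break toward the smallest P, because
integer multiples of the true ploidy fit equally well. In the full
pipeline the residual is evaluated on per-bin *segment means* (the ratio
series is segmented first; the CBS statistic is scale-invariant, so
breakpoints are identical whether found before or after ploidy scaling).
Raw per-bin evaluation makes noise enter R as (Pσ)² per bin, which tilts
the whole curve toward small P — at realistic shallow-WGS noise it
systematically halves ploidy-3 cells to 2. Segment means suppress the
noise term by segment length and restore recovery (±0.05 across seeds);
the `acd_ploidy` function itself accepts any per-bin vector, so both
behaviours are available.

**CBS.** Circular binary segmentation per chromosome on non-dropout bins:
the arc (i, j] maximizing Z = |mean_arc − mean_complement|/√(1/m + 1/k)
is found exhaustively (O(n²) via a cumulative-sum bridge; the global
noise scale cancels under permutation, so Z needs no variance estimate);
the split is accepted when its permutation p-value < α (default 0.01,
1000 permutations, sequential early rejection that leaves decisions
identical to the full test), and recursion continues. Segments shorter
than 3 bins are merged into the neighbour with the nearest mean
(switchable). Segment boundaries map back to the full bin vector, so
segments partition every bin; dropout bins inherit the enclosing segment
but are flagged missing in per-bin output.

**Integer profiles and detection.** Bins inherit round(segment mean) with
halves rounded away from zero (2.5 → 3); a per-bin rounding path exists
for bulk-style calling. A reference CNV event counts as detected when
≥ 50 % (`min_overlap`) of the bins whose midpoints fall inside it carry
the event's integer copy number; the 0.5 default is a design choice, as
is midpoint membership.

## QC metrics

MAD is the mean (or median, switchable — the two namings coexist in the
field) of |CN difference| over originally-adjacent non-dropout bin pairs,
never across chromosome boundaries, so whole-chromosome aneuploidy does
not inflate it. Cells pass at MAD ≤ 1 and dropout ratio ≤ 0.5, both
inclusive. Lorenz curves are computed at bin resolution (counts sorted
ascending; cumulative bin fraction vs cumulative read fraction), with
Gini = 1 − 2·AUC (trapezoidal); per-base Lorenz curves from pileups are
out of scope.

## SNV / allele drop-out

Analysis operates on allele-depth tables (VCF AD field or TSV) — the
upstream trimming/alignment/genotyping chain is established tooling, out
of scope. A site is heterozygous at MAF ≥ 5 % and depth ≥ 5 (single
cell) or MAF ≥ 20 % and depth ≥ 30 (bulk), thresholds inclusive; the bulk
rule is strictly nested in the single-cell rule. ADO is scored over
bulk-called het sites with cell depth ≥ a cutoff: a covered site drops
out when either allele has fewer than `alt_evidence_min` (default 1)
supporting reads. Reports span a cutoff ladder; an optional region mask
(e.g. the diploid segments from the CNV chain) restricts scoring.

For parameter recovery, the loss channel is isolated: one pot,
competition and jitter off, uniform mappability. Then a haplotype is
absent with probability p = `fragment_loss_prob` and
ADO = 2p(1−p)/(1−p²) = 2p/(1+p), so p̂ = ADO/(2−ADO); measured rates
match within Monte-Carlo error and zero loss yields exactly zero ADO.
With competition on, minority-share alleles in multi-template droplets
add a further finite-depth dropout channel (~0.5–8 % depending on depth
and occupancy) — a real phenomenon, which is why the isolation config
exists for calibration.

## Numerical and interface choices

- All genomic coordinates are 0-based half-open on disk (BED/TSV) except
  VCF (1-based), converted at the boundary; allele tables carry 1-based
  positions.
- One `numpy` Generator per simulation, seeded explicitly; every
  stochastic operation takes a seed. Identical config + seed gives
  byte-identical outputs.
- Degenerate inputs: empty alignment sets count zero everywhere; unknown
  chromosomes are skipped and counted, not fatal; all-equal series yield
  one segment; zero surviving fragments warn and return zeros; all-zero
  counts make the Lorenz curve undefined (error).
- The CLI is a thin wrapper over these functions (subcommands droplets,
  simulate, bin, count, cnv, qc, snv, run); config files are flat
  key = value with the same names as the Python defaults, CLI flags
  override, and every output directory gets a run-metadata JSON with the
  package version, seed and config hash.

## Limitations

Synthetic genomes are 10³–10⁴× smaller than real ones, so absolute MAD
and Gini values depend on the chosen depth-per-bin and are meaningful as
*orderings and trends*, not as calibrated predictions for a given
sequencing run. The competition model (one lognormal-share parameter for
both one-pot bias and droplet crowding) is the simplest mechanism that
reproduces the saturation-equalization picture; it is not a kinetic model
of phi-29 amplification. Allele-specific copy number, breakpoint
refinement below bin resolution, and polymerase error rates are out of
scope.
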