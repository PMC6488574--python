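"""End-to-end orchestration: simulate -> bin -> count -> call -> QC (-> SNV).

`analyze_cell` is the in-memory path used from Python; `run_pipeline`
drives the same chain from a flat configuration mapping and writes the
standard output files, which is what the command-line `run` subcommand
calls.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .binning import BinCounts, BinSet, build_dynamic_bins, count_reads, dropout_ratio
from .cnv import CopyNumberProfile, call_profile, detection_rate
from .genome import GenomeModel, TruthProfile, make_genome, make_truth_profile
from .qc import QCReport, qc_report
from .simulate import SimConfig, SimOutput, simulate_amplification

log = logging.getLogger("emdakit")

__all__ = ["CellResult", "analyze_cell", "run_pipeline", "DEFAULT_CONFIG"]


@dataclass
class CellResult:
    """Everything the calling chain produces for one cell."""

    sim: SimOutput | None
    binset: BinSet
    counts: BinCounts
    profile: CopyNumberProfile
    qc: QCReport

    @property
    def detection(self) -> float | None:
        if self.sim is None:
            return None
        return detection_rate(self.profile.integer_cn, self.sim.truth, self.binset)


def analyze_cell(
    genome: GenomeModel,
    sim: SimOutput,
    binset: BinSet | None = None,
    target_bin_size: int = 50_000,
    mapq_min: int = 15,
    gc_span: float = 0.3,
    ploidy_grid: tuple[float, float, float] = (1.5, 6.0, 0.05),
    cbs_alpha: float = 0.01,
    cbs_nperm: int = 1000,
    seed: int = 0,
) -> CellResult:
    """Run the full copy-number chain on one simulated (or loaded) cell."""
    if binset is None:
        binset = build_dynamic_bins(genome, target_bin_size)
    counts = count_reads(binset, sim.reads, mapq_min=mapq_min,
                         sample_id=sim.sample_id, total_reads=sim.total_reads)
    profile = call_profile(counts, binset, gc_span=gc_span,
                           ploidy_grid=ploidy_grid, cbs_alpha=cbs_alpha,
                           cbs_nperm=cbs_nperm, seed=seed)
    qc = qc_report(sim.sample_id, profile.scaled_cn, binset.chrom_labels,
                   counts, dropout_mask=profile.dropout_mask)
    return CellResult(sim=sim, binset=binset, counts=counts, profile=profile, qc=qc)


DEFAULT_CONFIG: dict = {
    # genome
    "n_chrom": 2,
    "chrom_length": 10_000_000,
    "window": 10_000,
    "n_het_sites": 0,
    # truth
    "n_events": 4,
    "event_min": 1_000_000,
    "event_max": 3_000_000,
    "cn_states": (1, 3),
    "baseline": 2,
    # amplification
    "n_cells": 1,
    "n_droplets": None,
    "fragment_length": 10_000,
    "fragment_loss_prob": 0.05,
    "tube_bias_sigma": 1.5,
    "within_droplet_cv": 0.2,
    "empty_droplet_background": 0.3,
    "gc_bias_c1": 0.0,
    "gc_bias_c2": 0.0,
    "total_reads": 200_000,
    "read_length": 100,
    # analysis
    "bin_size": 50_000,
    "mapq_min": 15,
    "gc_span": 0.3,
    "ploidy_grid": (1.5, 6.0, 0.05),
    "cbs_alpha": 0.01,
    "cbs_nperm": 1000,
    "seed": 0,
}


def _check_config(config: dict) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    unknown = [k for k in config if k not in cfg]
    if unknown:
        raise KeyError(f"unknown config keys: {unknown}")
    cfg.update(config)
    return cfg


def run_pipeline(config: dict, outdir: str | Path) -> list[CellResult]:
    """Simulate a cohort and run the full analysis, writing standard outputs.

    Per cell: counts TSV, per-bin profile TSV, segments TSV, QC JSON.
    Cohort-wide: bins BED, truth BED, QC summary TSV, run-metadata JSON.
    Deterministic for a fixed config (the seed drives everything).
    """
    cfg = _check_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    genome = make_genome(
        n_chrom=cfg["n_chrom"], chrom_length=cfg["chrom_length"],
        window=cfg["window"], n_het_sites=cfg["n_het_sites"], seed=cfg["seed"],
    )
    truth = make_truth_profile(
        genome, n_events=cfg["n_events"],
        size_range=(cfg["event_min"], cfg["event_max"]),
        cn_states=tuple(cfg["cn_states"]), baseline=cfg["baseline"],
        seed=cfg["seed"] + 1,
    )
    binset = build_dynamic_bins(genome, cfg["bin_size"])
    eio.write_bins_bed(binset, outdir / "bins.bed")
    eio.write_truth_bed(truth, outdir / "truth.bed")
    log.info("genome %d chrom x %.1f Mb, %d bins, %d truth events",
             cfg["n_chrom"], cfg["chrom_length"] / 1e6, len(binset), len(truth.events))

    results = []
    qc_rows = []
    for i in range(cfg["n_cells"]):
        sample = f"cell{i:02d}"
        sim_cfg = SimConfig(
            n_droplets=cfg["n_droplets"],
            fragment_length=cfg["fragment_length"],
            fragment_loss_prob=cfg["fragment_loss_prob"],
            tube_bias_sigma=cfg["tube_bias_sigma"],
            within_droplet_cv=cfg["within_droplet_cv"],
            empty_droplet_background=cfg["empty_droplet_background"],
            gc_bias_coefficients=(cfg["gc_bias_c1"], cfg["gc_bias_c2"]),
            total_reads=cfg["total_reads"], read_length=cfg["read_length"],
            seed=cfg["seed"] + 100 + i,
        )
        sim = simulate_amplification(genome, truth, sim_cfg, sample_id=sample)
        res = analyze_cell(
            genome, sim, binset=binset, mapq_min=cfg["mapq_min"],
            gc_span=cfg["gc_span"], ploidy_grid=tuple(cfg["ploidy_grid"]),
            cbs_alpha=cfg["cbs_alpha"], cbs_nperm=cfg["cbs_nperm"],
            seed=cfg["seed"] + 200 + i,
        )
        eio.write_counts_tsv(res.counts, binset, outdir / f"{sample}.counts.tsv")
        res.profile.to_frame().to_csv(outdir / f"{sample}.profile.tsv",
                                      sep="\t", index=False)
        eio.write_segments(res.profile.segments, binset,
                           outdir / f"{sample}.segments.tsv", sample_id=sample)
        if len(sim.allele_depths):
            eio.write_allele_table(sim.allele_depths,
                                   outdir / f"{sample}.alleles.tsv")
        import json
        (outdir / f"{sample}.qc.json").write_text(
            json.dumps(res.qc.to_dict(), indent=2) + "\n")
        qc_rows.append({**res.qc.to_dict(), "reasons": ";".join(res.qc.reasons),
                        "mapping_rate": sim.mapping_rate,
                        "detection_rate": res.detection,
                        "ploidy": res.profile.ploidy})
        log.info("%s: mapping %.3f, MAD %.3f, dropout %.3f, %s", sample,
                 sim.mapping_rate, res.qc.mad, res.qc.dropout,
                 "PASS" if res.qc.passed else "FAIL")
        results.append(res)

    pd.DataFrame(qc_rows).to_csv(outdir / "qc_summary.tsv", sep="\t", index=False)
    eio.write_run_metadata(outdir / "run_metadata.json", cfg, seed=cfg["seed"],
                           extra={"elapsed_s": round(time.time() - t0, 2),
                                  "n_cells": cfg["n_cells"]})
    return results
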