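import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import emdakit as ek

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """2 x 4 Mb genome, 10-kb windows, 400 het sites."""
    return ek.make_genome(
        n_chrom=2, chrom_length=4_000_000, window=10_000,
        n_het_sites=400, seed=7,
    )


@pytest.fixture(scope="session")
def uniform_genome():
    """Perfectly mappable 1 x 2 Mb genome (no GC/mappability structure)."""
    return ek.make_genome(
        n_chrom=1, chrom_length=2_000_000, window=10_000,
        gc_model={"sd": 0.0},
        mappability_model={"p_low": 0.0}, seed=3,
    )


@pytest.fixture(scope="session")
def small_binset(small_genome):
    return ek.build_dynamic_bins(small_genome, 50_000)


@pytest.fixture(scope="session")
def flat_truth():
    return ek.TruthProfile([], baseline_ploidy=2)


@pytest.fixture(scope="session")
def small_truth():
    """Two events on the 2 x 4 Mb genome, 50-kb aligned."""
    return ek.TruthProfile(
        [("chr1", 500_000, 1_500_000, 3), ("chr2", 2_000_000, 3_200_000, 1)],
        baseline_ploidy=2,
    )


@pytest.fixture(scope="session")
def emda_sim(small_genome, small_truth):
    cfg = ek.SimConfig(total_reads=60_000, seed=42)
    return ek.simulate_amplification(small_genome, small_truth, cfg)


def toy_alignments(rows):
    """(chrom, start, mapq) tuples -> alignment frame with 100-bp reads."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "mapq"])
    df["end"] = df["start"] + 100
    return df[["chrom", "start", "end", "mapq"]]
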