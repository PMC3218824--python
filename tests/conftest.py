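import numpy as np
import pandas as pd
import pytest

from methcompare.io_formats import GenomeSequence
from methcompare.methylome import call_methylation
from methcompare.synthetic_data import SimulationConfig, simulate_all


def mk_reads(rows):
    """Build an aligned-bisulfite-read table from
    (read_id, chrom, start, strand, bs_strand, seq) tuples."""
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "start", "strand", "bs_strand", "seq"]
    )


def mk_methylome(rows):
    """Build a methylome table from
    (chrom, pos, strand, context3, dinuc, meth, total, is_tacag) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "context3", "dinuc",
                 "meth_count", "total_count", "is_tacag"],
    )
    df["is_tacag"] = df["is_tacag"].astype(bool)
    return df


@pytest.fixture(scope="session")
def default_sim():
    """One three-line simulation under the default study conditions
    (coverage reduced to 20x to keep the suite quick)."""
    cfg = SimulationConfig(seed=0, coverage=20.0)
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def default_meths(default_sim):
    return {
        line: call_methylation(default_sim.reads[line], default_sim.genome)
        for line in default_sim.config.lines
    }


@pytest.fixture()
def tiny_genome():
    return GenomeSequence({"c1": "TTACAGTAACGATCGATTTACAGCCGGNNACGT"})
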