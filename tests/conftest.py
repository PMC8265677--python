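import numpy as np
import pandas as pd
import pytest

from sixma.genome_io import GeneModel, Genome
from sixma.modcalls import CALL_COLUMNS, CallSet
from sixma.synthetic import SimConfig, simulate_callsets, simulate_genome


def make_callset(rows, label="test"):
    """rows: (chrom, pos, strand, frac[, coverage, qv]) tuples."""
    full = [
        (r[0], r[1], r[2], r[4] if len(r) > 4 else 50.0, r[5] if len(r) > 5 else 40.0, r[3])
        for r in rows
    ]
    df = pd.DataFrame(full, columns=["chrom", "pos", "strand", "coverage", "qv", "frac"])
    return CallSet(label, df[CALL_COLUMNS])


@pytest.fixture
def tiny_genome():
    return Genome({"c1": "CATGCAAGATCATT", "c2": "GGCCATAT"})


@pytest.fixture(scope="session")
def sim_bundle():
    """A moderately sized deterministic simulation shared across tests."""
    cfg = SimConfig(seed=11, chrom_lengths=(80_000, 40_000))
    genome, genes = simulate_genome(cfg)
    cs_a, cs_b, truth = simulate_callsets(cfg, genome)
    return cfg, genome, genes, cs_a, cs_b, truth


@pytest.fixture
def plus_gene():
    return GeneModel("gp", "c1", 2, 10, "+")


def rng(seed=0):
    return np.random.default_rng(seed)
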