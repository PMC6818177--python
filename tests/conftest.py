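import numpy as np
import pandas as pd
import pytest

import epilineage as el
from epilineage import expression, regsignal


@pytest.fixture(scope="session")
def sim():
    """One default synthetic dataset shared by read-only tests."""
    return el.simulate(el.SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def expr_table(sim):
    lengths = pd.Series({g.gene_id: g.length_kb for g in sim.genes})
    return expression.ExpressionTable.from_counts(sim.expression_counts, lengths)


@pytest.fixture(scope="session")
def promoters(sim):
    return regsignal.promoter_regions(sim.genes, sim.genome)


def make_track(reads, cell="X", assay="mnase", total_mapped=None, genome=None):
    """ReadTrack from a list of (chrom, start, end) tuples."""
    by_chrom = {}
    for chrom, s, e in reads:
        by_chrom.setdefault(chrom, ([], []))
        by_chrom[chrom][0].append(s)
        by_chrom[chrom][1].append(e)
    arrays = {
        c: (np.array(s, dtype=np.int64), np.array(e, dtype=np.int64))
        for c, (s, e) in by_chrom.items()
    }
    if total_mapped is None:
        total_mapped = len(reads)
    return el.ReadTrack(cell, assay, arrays, total_mapped, genome=genome)


@pytest.fixture
def tiny_track():
    return make_track
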