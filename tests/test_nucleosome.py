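"""TSS-anchored occupancy profiles, NDR quantification and gene ordering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import epilineage as el
from epilineage import expression, nucleosome
from epilineage.core import GenomicInterval, GeneModel
from epilineage.nucleosome import (
    ndr_occupancy,
    order_genes_by_ndr,
    tss_profile,
    _ndr_window,
)


def gene(gene_id, tss, strand, length=2000, chrom="chr1"):
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + length, "+")
    else:
        iv = GenomicInterval(chrom, tss - length + 1, tss + 1, "-")
    return GeneModel(gene_id, iv, tss, length / 1000.0)


def test_profile_bin_index_oracle_on_both_strands(tiny_track):
    # plus strand: midpoint 4101 at tss 5000 -> offset -899 -> bin 10
    plus = gene("gp", 5000, "+")
    track = tiny_track([("chr1", 4096, 4106)], assay="mnase", total_mapped=10**6)
    prof = tss_profile(track, [plus])
    assert prof.values[0, 10] == pytest.approx(1.0)
    assert prof.values[0].sum() == pytest.approx(1.0)
    # minus strand mirror: midpoint 5899 -> oriented offset -899 -> bin 10
    minus = gene("gm", 5000, "-")
    track = tiny_track([("chr1", 5894, 5904)], assay="mnase", total_mapped=10**6)
    prof = tss_profile(track, [minus])
    assert prof.values[0, 10] == pytest.approx(1.0)


def test_profile_brute_force_oracle_random_reads(tiny_track):
    rng = np.random.default_rng(1)
    g = gene("g", 50_000, "-")
    mids = rng.integers(48_500, 51_500, 400)
    reads = [("chr1", int(m) - 5, int(m) + 5) for m in mids]
    prof = tss_profile(tiny_track(reads, assay="mnase", total_mapped=10**6), [g])
    expected = np.zeros(200)
    for m in mids:
        offset = g.tss - int(m)  # oriented: upstream is +genomic on minus strand
        b = (offset + 1000) // 10
        if 0 <= b < 200:
            expected[b] += 1
    assert np.allclose(prof.values[0], expected)


def test_profile_requires_mnase_and_handles_zero_reads(tiny_track):
    g = gene("g", 5000, "+")
    with pytest.raises(ValueError, match="MNase"):
        tss_profile(tiny_track([("chr1", 0, 10)], assay="h3k9ac"), [g])
    prof = tss_profile(tiny_track([("chr2", 0, 10)], assay="mnase"), [g])
    assert np.all(prof.values == 0)


def test_truncated_window_genes_are_flagged(tiny_track):
    g = gene("edge", 300, "+", length=600)
    genome = el.GenomeTable({"chr1": 100_000})
    track = tiny_track([("chr1", 10, 59)], assay="mnase")
    prof = tss_profile(track, [g], genome)
    assert "edge" in prof.truncated


def test_ndr_window_definition_and_mirror():
    assert _ndr_window(gene("gp", 1000, "+")) == (850, 1050)
    assert _ndr_window(gene("gm", 1000, "-", length=500)) == (951, 1151)


def test_ndr_mirror_by_explicit_reflection(tiny_track):
    """A read at oriented offset o counts for +/- genes symmetrically."""
    for offset in (-150, -1, 0, 49):
        gp, gm = gene("gp", 5000, "+"), gene("gm", 5000, "-")
        # midpoint at oriented offset: tss+offset (+) / tss-offset (-)
        tp = tiny_track([("chr1", 5000 + offset - 5, 5000 + offset + 5)], assay="mnase",
                        total_mapped=10**6)
        tm = tiny_track([("chr1", 5000 - offset - 5, 5000 - offset + 5)], assay="mnase",
                        total_mapped=10**6)
        assert ndr_occupancy(tp, [gp]).iloc[0] == ndr_occupancy(tm, [gm]).iloc[0] > 0
    for offset in (-151, 50):
        gp = gene("gp", 5000, "+")
        tp = tiny_track([("chr1", 5000 + offset - 5, 5000 + offset + 5)], assay="mnase",
                        total_mapped=10**6)
        assert ndr_occupancy(tp, [gp]).iloc[0] == 0


def test_uniform_density_gives_proportional_ndr_share(tiny_track):
    g = gene("g", 10_000, "+")
    reads = [("chr1", s, s + 10) for s in range(9000, 11000)]  # 1 per bp midpoint
    track = tiny_track(reads, assay="mnase", total_mapped=10**6)
    ndr = ndr_occupancy(track, [g]).iloc[0]
    window_total = tss_profile(track, [g]).values[0].sum()
    assert ndr / window_total == pytest.approx(200 / 2000, rel=0.02)


def test_order_genes_by_ndr_sort_and_ties():
    s = pd.Series({"a": 2.0, "b": 1.0, "c": 3.0})
    assert order_genes_by_ndr(s) == ["b", "a", "c"]
    ties = pd.Series({"z": 1.0, "a": 1.0, "m": 1.0})
    assert order_genes_by_ndr(ties) == ["a", "m", "z"]
    assert sorted(order_genes_by_ndr(s)) == sorted(s.index)


def test_profile_bins_partition_the_2kb_window(sim):
    genes = sim.genes[:50]
    track = sim.track("GNP", "mnase")
    prof = tss_profile(track, genes)
    window = [
        GenomicInterval(g.interval.chrom, g.tss - 1000, g.tss + 1000)
        if g.interval.strand == "+"
        else GenomicInterval(g.interval.chrom, g.tss - 999, g.tss + 1001)
        for g in genes
    ]
    from epilineage.core import count_reads, rpm_normalize

    totals = rpm_normalize(count_reads(track, window, "midpoint"), track.total_mapped)
    assert np.allclose(prof.values.sum(axis=1), totals)


def test_top_expression_decile_shows_ndr_dip(sim, expr_table):
    rpkm = expr_table.rpkm_values["NSC"]
    top = rpkm.sort_values().index[-100:]
    genes = [g for g in sim.genes if g.gene_id in set(top)]
    prof = tss_profile(sim.track("NSC", "mnase"), genes)
    mean = prof.values.mean(axis=0)
    ndr_bins = slice(85, 105)  # oriented offsets [-150, +50)
    assert mean[ndr_bins].min() == mean.min()


def test_expression_anticorrelates_with_ndr_occupancy(sim, expr_table):
    rhos = []
    for cell in el.CELL_TYPES:
        ndr = ndr_occupancy(sim.track(cell, "mnase"), sim.genes)
        rho = stats.spearmanr(
            expr_table.rpkm_values[cell].values, ndr.values
        ).statistic
        rhos.append(rho)
    assert max(rhos) <= -0.3
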