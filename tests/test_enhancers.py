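"""Sliding-window enhancer calling, target assignment, specificity and enrichment."""

from math import comb

import numpy as np
import pytest

import epilineage as el
from epilineage import chromstate, enhancers
from epilineage.core import GenomicInterval, GeneModel
from epilineage.enhancers import (
    _merge_intervals,
    assign_targets,
    call_enhancers,
    consensus_enhancers,
    gene_set_enrichment,
    read_gmt,
    specific_h3k9ac_enhancers,
    write_gmt,
)


def bg_track(make, rng, rate=0.01, length=1_000_000, extra=(), assay="h3k4me1"):
    n = rng.poisson(rate * length)
    mids = rng.integers(0, length - 49, n)
    reads = [("chr1", int(m), int(m) + 49) for m in mids] + list(extra)
    return make(reads, assay=assay, total_mapped=2_000_000)


def test_window_config_errors(tiny_track):
    genome = el.GenomeTable({"chr1": 10_000})
    track = tiny_track([("chr1", 0, 49)], assay="h3k4me1")
    for kwargs in ({"window": 0}, {"window": 500, "step": 600}):
        with pytest.raises(ValueError):
            call_enhancers(track, genome, [], **kwargs)
    with pytest.raises(ValueError, match="h3k4me1"):
        call_enhancers(
            tiny_track([("chr1", 0, 49)], assay="mnase"), genome, []
        )


def test_background_only_genome_yields_no_peaks(tiny_track):
    genome = el.GenomeTable({"chr1": 1_000_000})
    counts = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        counts.append(len(call_enhancers(bg_track(tiny_track, rng), genome, [])))
    assert np.mean(counts) <= 1


def test_planted_enhancer_recovered_with_reciprocal_overlap(tiny_track):
    genome = el.GenomeTable({"chr1": 1_000_000})
    rng = np.random.default_rng(1)
    planted = (500_000, 501_500)
    hot = rng.integers(planted[0], planted[1] - 49, 150)  # 10x background
    extra = [("chr1", int(m), int(m) + 49) for m in hot]
    es = call_enhancers(bg_track(tiny_track, rng, extra=extra), genome, [])
    assert len(es) >= 1
    best = max(
        min(
            (min(iv.end, planted[1]) - max(iv.start, planted[0]))
            / (planted[1] - planted[0]),
            (min(iv.end, planted[1]) - max(iv.start, planted[0])) / iv.width,
        )
        for iv in es.intervals
    )
    assert best >= 0.5


def test_peak_inside_promoter_is_discarded(tiny_track):
    genome = el.GenomeTable({"chr1": 1_000_000})
    rng = np.random.default_rng(2)
    hot = rng.integers(500_000, 501_500 - 49, 150)
    extra = [("chr1", int(m), int(m) + 49) for m in hot]
    promoter = [GenomicInterval("chr1", 499_000, 502_000)]
    es = call_enhancers(bg_track(tiny_track, rng, extra=extra), genome, promoter)
    assert all(not iv.overlaps(promoter[0]) for iv in es.intervals)
    assert len(es) == 0


def test_interval_merging_is_idempotent():
    ivs = [("chr1", 0, 100), ("chr1", 50, 150), ("chr1", 200, 300)]
    merged = [(c, s, e) for c, s, e, _ in _merge_intervals(ivs)]
    assert merged == [("chr1", 0, 150), ("chr1", 200, 300)]
    again = [(c, s, e) for c, s, e, _ in _merge_intervals(merged)]
    assert again == merged


def gene_at(gene_id, tss, strand="+"):
    iv = GenomicInterval("chr1", tss, tss + 500, "+") if strand == "+" else None
    return GeneModel(gene_id, iv, tss, 0.5)


def test_assign_targets_distance_rules():
    genes = [gene_at("near", 6500), gene_at("far", 20_000)]
    enh = [GenomicInterval("chr1", 5000, 6000)]
    t = assign_targets(enh, genes).table.iloc[0]
    assert (t["target"], t["distance"]) == ("near", 500)

    inside = assign_targets(enh, [gene_at("in", 5500)]).table.iloc[0]
    assert inside["distance"] == 0

    lone = assign_targets(enh, [gene_at("g", 16_001)]).table.iloc[0]
    assert not lone["assigned"]  # 16001 - 6000 = 10001 > 10 kb

    tie = assign_targets(
        [GenomicInterval("chr1", 5000, 6000)],
        [gene_at("b", 6500), gene_at("a", 4500)],
    ).table.iloc[0]
    assert tie["target"] == "a"  # equal distance 500, smaller gene_id wins
    assert (assign_targets(enh, genes).table["distance"] <= 10_000).all()


def test_consensus_is_the_merged_union(tiny_track):
    from epilineage.enhancers import Enhancer, EnhancerSet

    def es(cell, spans):
        return EnhancerSet(
            cell,
            [Enhancer(GenomicInterval("chr1", s, e), 1, 0.5, 0.5) for s, e in spans],
        )

    cons = consensus_enhancers(
        [es("A", [(0, 100), (500, 700)]), es("B", [(50, 200)])]
    )
    assert [(c.start, c.end) for c in cons] == [(0, 200), (500, 700)]
    with pytest.raises(ValueError):
        consensus_enhancers([es("A", [])])


def test_specific_h3k9ac_split_identity_and_disjoint():
    from epilineage.enhancers import Enhancer, EnhancerSet

    def es(cell, spans):
        return EnhancerSet(
            cell,
            [Enhancer(GenomicInterval("chr1", s, e), 1, 0.5, 0.5) for s, e in spans],
        )

    a = es("A", [(0, 100), (200, 300)])
    same = specific_h3k9ac_enhancers(a, [True, True], a, [True, True])
    assert not same["a_specific"] and not same["b_specific"]
    assert len(same["shared"]) == 2

    b = es("B", [(400, 500)])
    disjoint = specific_h3k9ac_enhancers(a, [True, True], b, [True])
    assert len(disjoint["a_specific"]) == 2 and len(disjoint["b_specific"]) == 1
    assert not disjoint["shared"]


def test_planted_specific_enhancers_classified_correctly(sim, promoters):
    maps = {
        c: chromstate.state_map_from_tracks(
            sim.track(c, "h3k9ac"), sim.track(c, "h3k27me3"), sim.genome
        )
        for c in ("Neuron", "Glia")
    }
    sets = {
        c: call_enhancers(sim.track(c, "h3k4me1"), sim.genome, promoters)
        for c in ("Neuron", "Glia")
    }
    pos = {c: enhancers.h3k9ac_positive(sets[c], maps[c]) for c in maps}
    split = specific_h3k9ac_enhancers(
        sets["Neuron"], pos["Neuron"], sets["Glia"], pos["Glia"]
    )

    def recip(iv, s, e):
        ov = max(0, min(iv.end, e) - max(iv.start, s))
        return min(ov / (iv.end - iv.start), ov / (e - s))

    for cls, key in (("neuron_specific", "a_specific"), ("glia_specific", "b_specific")):
        planted = [
            r for r in sim.truth.enhancers.itertuples() if r.enh_class == cls
        ]
        hit = sum(
            1
            for r in planted
            if any(recip(iv, r.start, r.end) >= 0.5 for iv in split[key])
        )
        assert hit / len(planted) >= 0.9


def test_hypergeometric_enrichment_exhaustive_oracle():
    universe = [f"g{i}" for i in range(20)]
    sets = {"s": universe[:5]}
    res = gene_set_enrichment(universe[:5], sets, universe)
    assert res.loc[0, "pvalue"] == pytest.approx(1 / comb(20, 5))

    none = gene_set_enrichment(universe[10:12], {"s": universe[:5]}, universe)
    assert none.loc[0, "pvalue"] == pytest.approx(1.0)

    saturated = gene_set_enrichment(universe, {"s": universe[:5]}, universe)
    assert saturated.loc[0, "pvalue"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        gene_set_enrichment(["g"], {}, [])


def test_gmt_round_trip(tmp_path):
    sets = {"a": ["g1", "g2"], "b": ["g3"]}
    p = tmp_path / "sets.gmt"
    write_gmt(sets, p)
    assert read_gmt(p) == sets


def test_enrichment_flags_top_five():
    universe = [f"g{i}" for i in range(100)]
    gene_sets = {f"s{i}": universe[i : i + 10] for i in range(8)}
    res = gene_set_enrichment(universe[:10], gene_sets, universe)
    assert res["top"].sum() == 5
    assert res["pvalue"].is_monotonic_increasing
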