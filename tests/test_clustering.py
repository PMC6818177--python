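"""Z-scoring, agglomerative cell-type clustering and topology comparison."""

import numpy as np
import pytest

from epilineage.clustering import (
    Dendrogram,
    compare_topology,
    has_bipartition,
    hcluster_cells,
    zscore_rows,
)
from epilineage.core import SignalMatrix
from epilineage.simulate import LineageTree


def matrix(values, cols=None, rows=None):
    values = np.asarray(values, dtype=float)
    rows = rows or [f"r{i}" for i in range(values.shape[0])]
    cols = cols or [f"c{i}" for i in range(values.shape[1])]
    return SignalMatrix(rows, cols, values)


def test_zscore_population_sd_convention():
    z = zscore_rows(matrix([[2, 4, 6, 8]]))
    sd = np.sqrt(5.0)  # population sd of [2,4,6,8]
    assert np.allclose(z.values[0], (np.array([2, 4, 6, 8]) - 5) / sd)


def test_zscore_drops_constant_rows_and_normalises():
    m = matrix([[1, 1, 1], [1, 2, 3], [5, 0, 1]])
    z = zscore_rows(m)
    assert z.row_ids == ["r1", "r2"]
    assert np.allclose(z.values.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(z.values.std(axis=1), 1, atol=1e-12)
    with pytest.raises(ValueError):
        zscore_rows(matrix([[3, 3, 3]]))


def test_identical_columns_merge_first_at_height_zero():
    m = matrix(np.column_stack([[1, 2, 3], [1, 2, 3], [9, 9, 9.0]]), cols=["A", "B", "C"])
    dend = hcluster_cells(m)
    a, b, h = dend.merges[0]
    assert a | b == {"A", "B"} and h == 0.0


def test_row_permutation_leaves_dendrogram_unchanged():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(30, 4))
    m1 = matrix(values, cols=list("ABCD"))
    m2 = matrix(values[rng.permutation(30)], cols=list("ABCD"))
    d1, d2 = hcluster_cells(m1), hcluster_cells(m2)
    assert d1.cluster_sets == d2.cluster_sets
    assert np.allclose(d1.heights, d2.heights)


def test_complete_linkage_agrees_with_hand_agglomeration():
    """Planted distances d(AB) < d(ABC) < d(ABCD): caterpillar merge order."""
    # coordinates on a line: A=0, B=1, C=4, D=20
    m = matrix(np.array([[0.0, 1.0, 4.0, 20.0]]), cols=list("ABCD"))
    # single row is constant-variance-free after zscore; use two rows
    m = matrix(
        np.array([[0.0, 1.0, 4.0, 20.0], [0.0, 1.0, 4.0, 20.0]]), cols=list("ABCD")
    )
    dend = hcluster_cells(m)
    assert dend.cluster_sets[0] == {"A", "B"}
    assert dend.cluster_sets[1] == {"A", "B", "C"}
    assert dend.heights == sorted(dend.heights)


def test_cluster_requires_three_columns():
    with pytest.raises(ValueError):
        hcluster_cells(matrix(np.ones((3, 2))))


def reference():
    return LineageTree()


def test_compare_topology_identity_and_mismatch():
    cat = Dendrogram(
        ["GNP", "Glia", "NSC", "Neuron"],
        [
            (frozenset({"NSC"}), frozenset({"GNP"}), 1.0),
            (frozenset({"NSC", "GNP"}), frozenset({"Glia"}), 2.0),
            (frozenset({"NSC", "GNP", "Glia"}), frozenset({"Neuron"}), 3.0),
        ],
    )
    comp = compare_topology(cat, reference())
    assert comp.exact_match and comp.nested_order_match and not comp.unresolved

    swapped = Dendrogram(
        ["GNP", "Glia", "NSC", "Neuron"],
        [
            (frozenset({"NSC"}), frozenset({"GNP"}), 1.0),
            (frozenset({"NSC", "GNP"}), frozenset({"Neuron"}), 2.0),
            (frozenset({"NSC", "GNP", "Neuron"}), frozenset({"Glia"}), 3.0),
        ],
    )
    comp = compare_topology(swapped, reference())
    # both caterpillars induce the same single bipartition, so only the
    # merge-order (nesting) check can tell them apart
    assert comp.exact_match
    assert not comp.nested_order_match


def test_balanced_tree_has_progenitor_bipartition_but_not_nested_order():
    balanced = Dendrogram(
        ["GNP", "Glia", "NSC", "Neuron"],
        [
            (frozenset({"NSC"}), frozenset({"GNP"}), 1.0),
            (frozenset({"Glia"}), frozenset({"Neuron"}), 1.5),
            (frozenset({"NSC", "GNP"}), frozenset({"Glia", "Neuron"}), 3.0),
        ],
    )
    comp = compare_topology(balanced, reference())
    assert comp.bipartition_match[next(iter(comp.reference_bipartitions))]
    assert not comp.nested_order_match
    assert has_bipartition(balanced, {"NSC", "GNP"})


def test_all_equal_heights_flagged_unresolved():
    star = Dendrogram(
        ["A", "B", "C", "D"],
        [
            (frozenset({"A"}), frozenset({"B"}), 1.0),
            (frozenset({"A", "B"}), frozenset({"C"}), 1.0),
            (frozenset({"A", "B", "C"}), frozenset({"D"}), 1.0 + 1e-12),
        ],
    )
    assert star.unresolved
    ref = (((("A", "B"), "C"), "D"))
    comp = compare_topology(star, ref)
    assert comp.unresolved and not comp.exact_match


def test_leaf_mismatch_raises():
    d = Dendrogram(
        ["A", "B", "C"],
        [
            (frozenset({"A"}), frozenset({"B"}), 1.0),
            (frozenset({"A", "B"}), frozenset({"C"}), 2.0),
        ],
    )
    with pytest.raises(ValueError, match="leaf"):
        compare_topology(d, reference())


def test_linkage_choice_does_not_change_recovered_topology(sim):
    """Complete and average linkage agree on the H3K27me3 promoter topology."""
    import epilineage as el
    from epilineage import regsignal

    promoters = regsignal.promoter_regions(sim.genes, sim.genome)
    m = regsignal.signal_matrix(
        [sim.track(c, "h3k27me3") for c in el.CELL_TYPES],
        promoters,
        row_ids=[g.gene_id for g in sim.genes],
    )
    z = zscore_rows(m)
    complete = hcluster_cells(z, "complete")
    average = hcluster_cells(z, "average")
    assert complete.cluster_sets == average.cluster_sets


def test_newick_export_contains_all_leaves_and_heights():
    m = matrix(np.random.default_rng(3).normal(size=(20, 4)), cols=list("ABCD"))
    dend = hcluster_cells(m)
    nwk = dend.newick()
    assert nwk.endswith(";") and all(l in nwk for l in "ABCD")
    import dendropy

    tree = dendropy.Tree.get(data=nwk, schema="newick")
    assert {t.label for t in tree.taxon_namespace} == set("ABCD")
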