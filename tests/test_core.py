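"""Coordinate conventions, format I/O and read counting against brute-force oracles."""

import numpy as np
import pytest

import epilineage as el
from epilineage.core import (
    GenomicInterval,
    ParseError,
    count_reads,
    read_bed,
    read_gtf_genes,
    read_matrix,
    rpm_normalize,
    write_matrix,
)


# ---------------------------------------------------------------------- BED

def test_read_bed_preserves_half_open_coordinates(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\nchr1\t100\t200\tx\t0\t-\ntrack name=foo\n")
    ivs = read_bed(p)
    assert ivs[0] == GenomicInterval("chr1", 100, 200, ".")
    assert ivs[1].strand == "-"
    assert len(ivs) == 2  # track line skipped


@pytest.mark.parametrize(
    "line", ["chr1\t200\t100", "chr1\tx\t100", "chr1\t100"]
)
def test_read_bed_malformed_line_names_line_number(tmp_path, line):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t0\t10\n" + line + "\n")
    with pytest.raises(ParseError, match=":2"):
        read_bed(p)


def test_bed_round_trip_is_identity(tmp_path):
    ivs = [
        GenomicInterval("chr1", 0, 10, "+"),
        GenomicInterval("chr2", 5, 6, "-"),
        GenomicInterval("chr1", 100, 1000, "."),
    ]
    p = tmp_path / "rt.bed"
    el.write_bed(ivs, p, names=["a", "b", "c"], scores=[1, 2, 3])
    assert read_bed(p) == ivs


# ---------------------------------------------------------------------- GTF

def _gtf_line(chrom, feat, start1, end1, strand, gene, tx=None):
    attrs = f'gene_id "{gene}";'
    if tx:
        attrs += f' transcript_id "{tx}";'
    return f"{chrom}\tsrc\t{feat}\t{start1}\t{end1}\t.\t{strand}\t.\t{attrs}\n"


def test_gtf_coordinates_and_tss_by_strand(tmp_path):
    p = tmp_path / "g.gtf"
    p.write_text(
        _gtf_line("chr1", "transcript", 1001, 2000, "+", "gp")
        + _gtf_line("chr1", "transcript", 1001, 2000, "-", "gm")
    )
    genes = {g.gene_id: g for g in read_gtf_genes(p)}
    assert genes["gp"].interval.start == 1000 and genes["gp"].interval.end == 2000
    assert genes["gp"].tss == 1000
    assert genes["gm"].tss == 1999


def test_gtf_multi_transcript_collapses_to_longest_exonic(tmp_path):
    p = tmp_path / "g.gtf"
    lines = (
        _gtf_line("chr1", "exon", 1001, 1600, "+", "g", "t1")
        + _gtf_line("chr1", "exon", 2001, 2600, "+", "g", "t1")  # t1: 1.2 kb
        + _gtf_line("chr1", "exon", 1001, 1800, "+", "g", "t2")  # t2: 0.8 kb
    )
    p.write_text(lines)
    (g,) = read_gtf_genes(p)
    assert g.length_kb == pytest.approx(1.2)
    assert (g.interval.start, g.interval.end) == (1000, 2600)


def test_gtf_missing_gene_id_and_strand_conflict_raise(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text('chr1\ts\ttranscript\t1\t10\t.\t+\t.\tfoo "bar";\n')
    with pytest.raises(ParseError, match="gene_id"):
        read_gtf_genes(p)
    p2 = tmp_path / "bad2.gtf"
    p2.write_text(
        _gtf_line("chr1", "transcript", 1, 10, "+", "g")
        + _gtf_line("chr1", "transcript", 20, 30, "-", "g")
    )
    with pytest.raises(ParseError, match="strand"):
        read_gtf_genes(p2)


def test_gtf_round_trip_through_writer(tmp_path):
    iv = GenomicInterval("chr2", 4999, 8000, "-")
    gene = el.GeneModel.from_span("gX", iv)
    p = tmp_path / "rt.gtf"
    el.write_gtf([gene], p)
    (back,) = read_gtf_genes(p)
    assert back.interval == iv and back.tss == gene.tss
    assert back.length_kb == pytest.approx(gene.length_kb)


# ------------------------------------------------------------------ counting

def test_count_reads_midpoint_and_overlap_definitions(tiny_track):
    track = tiny_track([("chr1", 95, 105)])
    assert count_reads(track, [GenomicInterval("chr1", 100, 110)], "midpoint")[0] == 1
    assert count_reads(track, [GenomicInterval("chr1", 100, 110)], "overlap")[0] == 1
    assert count_reads(track, [GenomicInterval("chr1", 110, 120)], "overlap")[0] == 0
    assert count_reads(track, [], "midpoint").size == 0


def brute_force_counts(reads, regions, mode):
    out = []
    for r in regions:
        c = 0
        for chrom, s, e in reads:
            if chrom != r.chrom:
                continue
            if mode == "midpoint":
                c += r.start <= (s + e) // 2 < r.end
            else:
                c += s < r.end and r.start < e
        out.append(c)
    return np.array(out)


@pytest.mark.parametrize("mode", ["midpoint", "overlap"])
def test_count_reads_matches_brute_force_on_random_instances(tiny_track, mode):
    rng = np.random.default_rng(42)
    for _ in range(10):
        starts = rng.integers(0, 5000, 200)
        lengths = rng.integers(1, 300, 200)
        reads = [("chr1", int(s), int(s + l)) for s, l in zip(starts, lengths)]
        regions = [
            GenomicInterval("chr1", int(a), int(a + w))
            for a, w in zip(rng.integers(0, 5000, 30), rng.integers(1, 800, 30))
        ]
        track = tiny_track(reads)
        got = count_reads(track, regions, mode)
        assert np.array_equal(got, brute_force_counts(reads, regions, mode))


def test_midpoint_counting_conserves_reads_over_a_partition(tiny_track):
    rng = np.random.default_rng(7)
    reads = [("chr1", int(s), int(s) + 10) for s in rng.integers(0, 990, 1000)]
    bins = [GenomicInterval("chr1", i * 100, (i + 1) * 100) for i in range(10)]
    track = tiny_track(reads)
    assert count_reads(track, bins, "midpoint").sum() == 1000


# ---------------------------------------------------------------- RPM / matrix

def test_rpm_normalize_formula_and_linearity():
    assert rpm_normalize(50, 10_000_000)[()] == pytest.approx(5.0)
    assert rpm_normalize(0, 123)[()] == 0.0
    assert np.allclose(rpm_normalize([1, 2, 3], 10**6), [1.0, 2.0, 3.0])
    a, b = np.array([3, 4.0]), np.array([1, 9.0])
    assert np.allclose(
        rpm_normalize(a + b, 5000), rpm_normalize(a, 5000) + rpm_normalize(b, 5000)
    )
    with pytest.raises(ValueError):
        rpm_normalize([1], 0)


def test_matrix_round_trip_and_precision(tmp_path):
    m = el.SignalMatrix(
        ["r1", "r2", "r3"], list("abcd"), np.arange(12).reshape(3, 4) + 1 / 3.0
    )
    p = tmp_path / "m.tsv"
    write_matrix(m, p)
    back = read_matrix(p)
    assert back.row_ids == m.row_ids and back.col_ids == m.col_ids
    assert np.allclose(back.values, m.values, atol=1e-10)

    empty = el.SignalMatrix([], ["a", "b"], np.empty((0, 2)))
    write_matrix(empty, tmp_path / "e.tsv")
    back = read_matrix(tmp_path / "e.tsv")
    assert back.shape == (0, 2)


def test_matrix_ragged_rows_raise(tmp_path):
    p = tmp_path / "ragged.tsv"
    p.write_text("id\ta\tb\nr1\t1\t2\nr2\t1\n")
    with pytest.raises(ParseError, match=":3"):
        read_matrix(p)


def test_read_track_invariants():
    with pytest.raises(ValueError, match="total_mapped"):
        el.ReadTrack(
            "X", "mnase",
            {"chr1": (np.array([0, 5]), np.array([10, 15]))}, total_mapped=1,
        )
    genome = el.GenomeTable({"chr1": 100})
    with pytest.raises(ValueError, match="not in genome"):
        el.ReadTrack(
            "X", "mnase", {"chr2": (np.array([0]), np.array([10]))}, 1, genome=genome
        )
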