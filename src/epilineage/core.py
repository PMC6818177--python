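"""Shared domain types, coordinate conventions, standard-format I/O and read counting.

All internal coordinates are 0-based half-open (BED-native). GTF's 1-based
closed coordinates are converted at the parsing boundary and restored on
export. Reads are counted either by midpoint (``floor((start+end)/2)``, a
dyad proxy suited to fine-binned MNase profiles) or by >=1 bp overlap
(suited to broad regions such as promoters, enhancers and chromatin-state
bins).
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ASSAYS = ("mnase", "h3k9ac", "h3k27me3", "h3k4me1")
HM_ASSAYS = ("h3k9ac", "h3k27me3", "h3k4me1")


class ParseError(ValueError):
    """Malformed record in an input file; message carries the line number."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """One gene collapsed to a single span, TSS and exonic length.

    The TSS is ``interval.start`` on the plus strand and ``interval.end - 1``
    on the minus strand; ``length_kb`` is the exonic length in kilobases used
    for RPKM.
    """

    gene_id: str
    interval: GenomicInterval
    tss: int
    length_kb: float

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.tss < self.interval.end):
            raise ValueError(f"TSS {self.tss} outside {self.interval}")
        if self.length_kb <= 0:
            raise ValueError("length_kb must be > 0")

    @classmethod
    def from_span(
        cls, gene_id: str, interval: GenomicInterval, length_kb: float | None = None
    ) -> "GeneModel":
        """Build a GeneModel deriving the TSS from the strand."""
        if interval.strand not in ("+", "-"):
            raise ValueError("gene interval must be stranded")
        tss = interval.start if interval.strand == "+" else interval.end - 1
        if length_kb is None:
            length_kb = interval.width / 1000.0
        return cls(gene_id, interval, tss, length_kb)


class GenomeTable(Mapping):
    """Chromosome name -> length (bp)."""

    def __init__(self, lengths: Mapping[str, int]):
        for chrom, n in lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {n}")
        self._lengths = dict(lengths)

    def __getitem__(self, key: str) -> int:
        return self._lengths[key]

    def __iter__(self):
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, n in self._lengths.items():
                fh.write(f"{chrom}\t{n}\n")

    @classmethod
    def read_tsv(cls, path) -> "GenomeTable":
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise ParseError(f"{path}:{i}: expected 2 columns")
                try:
                    lengths[parts[0]] = int(parts[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{i}: bad length {parts[1]!r}") from exc
        return cls(lengths)


class ReadTrack:
    """Aligned reads of one cell type x one assay, stored per chromosome.

    Reads are kept as paired (start, end) arrays sorted by start; sorted end
    and midpoint arrays are cached for counting. ``total_mapped`` is the
    library's total uniquely mapped read count (the RPM denominator), which
    may exceed the number of reads materialised in the track.
    """

    def __init__(
        self,
        cell_type: str,
        assay: str,
        reads_by_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]],
        total_mapped: int,
        genome: GenomeTable | None = None,
    ):
        if assay not in ASSAYS:
            raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
        self.cell_type = cell_type
        self.assay = assay
        self._data: dict[str, dict[str, np.ndarray]] = {}
        n_total = 0
        for chrom, (starts, ends) in reads_by_chrom.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            if starts.shape != ends.shape:
                raise ValueError("starts/ends shape mismatch")
            if starts.size and np.any(starts >= ends):
                raise ValueError(f"reads with start >= end on {chrom}")
            if genome is not None:
                if chrom not in genome:
                    raise ValueError(f"chromosome {chrom} not in genome table")
                if starts.size and (starts.min() < 0 or ends.max() > genome[chrom]):
                    raise ValueError(f"reads outside chromosome bounds on {chrom}")
            if starts.size and np.any(starts[1:] < starts[:-1]):
                order = np.argsort(starts, kind="stable")
                starts, ends = starts[order], ends[order]
            self._data[chrom] = {"starts": starts, "ends": ends}
            n_total += starts.size
        if total_mapped < n_total:
            raise ValueError(
                f"total_mapped ({total_mapped}) < number of reads ({n_total})"
            )
        self.total_mapped = int(total_mapped)
        self.n_reads = n_total

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def reads(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        d = self._data.get(chrom)
        if d is None:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return d["starts"], d["ends"]

    def _sorted(self, chrom: str, key: str) -> np.ndarray:
        """Cached ascending array of 'mids' or 'ends_sorted' for a chromosome."""
        d = self._data.get(chrom)
        if d is None:
            return np.empty(0, dtype=np.int64)
        if key not in d:
            if key == "mids":
                d[key] = np.sort((d["starts"] + d["ends"]) // 2)
            elif key == "ends_sorted":
                d[key] = np.sort(d["ends"])
            else:  # pragma: no cover
                raise KeyError(key)
        return d[key]

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self._data:
                starts, ends = self.reads(chrom)
                for s, e in zip(starts.tolist(), ends.tolist()):
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    @classmethod
    def from_bed(
        cls,
        path,
        cell_type: str,
        assay: str,
        total_mapped: int | None = None,
        genome: GenomeTable | None = None,
    ) -> "ReadTrack":
        # fast path: plain 3+-column BED without header lines
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], comment="#",
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
        arrays = {
            str(chrom): (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
            )
            for chrom, sub in df.groupby("chrom", sort=True)
        }
        if total_mapped is None:
            total_mapped = len(df)
        return cls(cell_type, assay, arrays, total_mapped, genome=genome)


class SignalMatrix:
    """Real-valued matrix of genes/enhancers (rows) x cell types or bins (columns)."""

    UNITS = ("RPM", "RPKM", "zscore", "count")

    def __init__(
        self,
        row_ids: Iterable[str],
        col_ids: Iterable[str],
        values: np.ndarray,
        units: str = "count",
    ):
        self.row_ids = [str(r) for r in row_ids]
        self.col_ids = [str(c) for c in col_ids]
        self.values = np.asarray(values, dtype=float)
        if units not in self.UNITS:
            raise ValueError(f"units must be one of {self.UNITS}")
        self.units = units
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} cols"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("SignalMatrix must not contain missing values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def col(self, label: str) -> np.ndarray:
        return self.values[:, self.col_ids.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def write_tsv(self, path) -> None:
        write_matrix(self, path)

    @classmethod
    def read_tsv(cls, path, units: str = "count") -> "SignalMatrix":
        return read_matrix(path, units=units)


# ---------------------------------------------------------------------------
# Standard-format I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Parse BED3/BED6 into intervals, preserving 0-based half-open coordinates.

    Column 6 is used as strand when present; ``track``/``browser``/comment
    lines are skipped.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{i}: expected >=3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(parts[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from exc
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path,
    names: Iterable[str] | None = None,
    scores: Iterable[float] | None = None,
) -> None:
    """Write BED3 (or BED6 when names/scores are given)."""
    intervals = list(intervals)
    names = list(names) if names is not None else None
    scores = list(scores) if scores is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is None and scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else "."
                score = f"{scores[i]:g}" if scores is not None else "0"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def _parse_gtf_attributes(text: str, path, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise ParseError(f"{path}:{lineno}: malformed attribute {chunk!r}")
        key, value = chunk.split(" ", 1)
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_genes(path) -> list[GeneModel]:
    """Parse GTF2.2 into one GeneModel per gene_id.

    Coordinates are converted from GTF's 1-based closed to 0-based half-open.
    Multi-transcript genes collapse to the span of the transcript with the
    largest exonic length, whose exonic length also provides ``length_kb``.
    Transcripts without exon features use their span length.
    """
    # per gene: strand, per transcript: span + exon bp
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{i}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attr_text = parts[:9]
            if feature not in ("gene", "transcript", "exon"):
                continue
            try:
                start0, end0 = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
            if start0 < 0 or start0 >= end0:
                raise ParseError(f"{path}:{i}: invalid coordinates {start1}..{end1}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{i}: gene features require +/- strand")
            attrs = _parse_gtf_attributes(attr_text, path, i)
            if "gene_id" not in attrs:
                raise ParseError(f"{path}:{i}: missing gene_id attribute")
            gid = attrs["gene_id"]
            rec = genes.setdefault(
                gid, {"chrom": chrom, "strand": strand, "transcripts": {}}
            )
            if rec["strand"] != strand:
                raise ParseError(
                    f"{path}:{i}: gene_id {gid!r} appears on conflicting strands"
                )
            if rec["chrom"] != chrom:
                raise ParseError(
                    f"{path}:{i}: gene_id {gid!r} appears on multiple chromosomes"
                )
            tid = attrs.get("transcript_id", gid)
            tx = rec["transcripts"].setdefault(
                tid, {"start": start0, "end": end0, "exon_bp": 0}
            )
            tx["start"] = min(tx["start"], start0)
            tx["end"] = max(tx["end"], end0)
            if feature == "exon":
                tx["exon_bp"] += end0 - start0
    out: list[GeneModel] = []
    for gid, rec in genes.items():
        best = None
        for tx in rec["transcripts"].values():
            exon_bp = tx["exon_bp"] if tx["exon_bp"] > 0 else tx["end"] - tx["start"]
            if best is None or exon_bp > best[0]:
                best = (exon_bp, tx["start"], tx["end"])
        exon_bp, start, end = best
        interval = GenomicInterval(rec["chrom"], start, end, rec["strand"])
        out.append(GeneModel.from_span(gid, interval, length_kb=exon_bp / 1000.0))
    return out


def write_gtf(genes: Iterable[GeneModel], path) -> None:
    """Write one transcript with one exon per gene (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            for feature in ("transcript", "exon"):
                fh.write(
                    f"{iv.chrom}\tepilineage\t{feature}\t{iv.start + 1}\t{iv.end}\t."
                    f"\t{iv.strand}\t.\t{attrs}\n"
                )


def write_matrix(matrix: SignalMatrix, path) -> None:
    """TSV with a header of col_ids and a first column of row_ids (12 significant digits)."""
    buf = io.StringIO()
    buf.write("id\t" + "\t".join(matrix.col_ids) + "\n")
    for rid, row in zip(matrix.row_ids, matrix.values):
        buf.write(rid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_matrix(path, units: str = "count") -> SignalMatrix:
    ncols = None
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ParseError(f"{path}:1: empty file")
        col_ids = header.rstrip("\n").split("\t")[1:]
        ncols = len(col_ids)
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for i, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncols + 1:
                raise ParseError(
                    f"{path}:{i}: expected {ncols + 1} columns, got {len(parts)}"
                )
            row_ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-numeric value") from exc
    values = np.array(rows, dtype=float) if rows else np.empty((0, ncols))
    return SignalMatrix(row_ids, col_ids, values, units=units)


# ---------------------------------------------------------------------------
# Counting and normalisation
# ---------------------------------------------------------------------------

def count_reads(
    track: ReadTrack, regions: list[GenomicInterval], mode: str = "midpoint"
) -> np.ndarray:
    """Count reads per region, by midpoint or by >=1 bp overlap.

    Midpoint mode counts a read iff floor((start+end)/2) lies in the region;
    overlap mode iff the read overlaps the region by at least one bp. A read
    may count in several overlapping regions. Both modes run in O(log n) per
    region via sorted-array rank queries: the number of overlapping reads is
    #{start < region.end} - #{end <= region.start}, which is exact because
    every read satisfies start < end.
    """
    if mode not in ("midpoint", "overlap"):
        raise ValueError(f"mode must be 'midpoint' or 'overlap', got {mode!r}")
    counts = np.zeros(len(regions), dtype=np.int64)
    if not regions:
        return counts
    chroms = np.array([r.chrom for r in regions])
    starts = np.array([r.start for r in regions], dtype=np.int64)
    ends = np.array([r.end for r in regions], dtype=np.int64)
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        if mode == "midpoint":
            mids = track._sorted(chrom, "mids")
            counts[mask] = np.searchsorted(
                mids, ends[mask], side="left"
            ) - np.searchsorted(mids, starts[mask], side="left")
        else:
            read_starts, _ = track.reads(chrom)
            read_ends = track._sorted(chrom, "ends_sorted")
            counts[mask] = np.searchsorted(
                read_starts, ends[mask], side="left"
            ) - np.searchsorted(read_ends, starts[mask], side="right")
    return counts


def count_reads_arrays(
    track: ReadTrack,
    chrom: str,
    starts: np.ndarray,
    ends: np.ndarray,
    mode: str = "midpoint",
) -> np.ndarray:
    """Vectorised single-chromosome variant of :func:`count_reads`."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if mode == "midpoint":
        mids = track._sorted(chrom, "mids")
        return np.searchsorted(mids, ends, side="left") - np.searchsorted(
            mids, starts, side="left"
        )
    if mode == "overlap":
        read_starts, _ = track.reads(chrom)
        read_ends = track._sorted(chrom, "ends_sorted")
        return np.searchsorted(read_starts, ends, side="left") - np.searchsorted(
            read_ends, starts, side="right"
        )
    raise ValueError(f"mode must be 'midpoint' or 'overlap', got {mode!r}")


def rpm_normalize(counts, total_mapped: int) -> np.ndarray:
    """Reads per million mapped reads: count * 1e6 / total_mapped."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    return np.asarray(counts, dtype=float) * 1.0e6 / float(total_mapped)
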