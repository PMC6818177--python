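"""Two-mark chromatin-state classification and state-transition flows.

Each chromosome is tiled with 200 bp bins. H3K9ac and H3K27me3 tracks are
binarised independently against a global Poisson background: with lambda
the genome-wide mean reads per bin (overlap counting), a bin is marked when
its count k has upper-tail probability P(X >= k | lambda) <= p_threshold
(default 1e-4). The two binary tracks combine into four states -- H3K9ac+,
H3K27me3+, both, unmarked -- and per-bin state labels of two cell types
form a 4x4 transition (alluvial) contingency.

A trained multi-state HMM would additionally smooth along the genome; an
optional 3-bin majority filter is provided for that purpose and is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GenomicInterval,
    GenomeTable,
    ReadTrack,
    count_reads_arrays,
    write_bed,
)

STATE_LABELS = ("H3K9ac+", "H3K27me3+", "both", "unmarked")
BIN_BP = 200

# state code = k9 + 2*k27: 0 -> unmarked, 1 -> H3K9ac+, 2 -> H3K27me3+, 3 -> both
_CODE_TO_LABEL = {0: "unmarked", 1: "H3K9ac+", 2: "H3K27me3+", 3: "both"}


def genome_bins(genome: GenomeTable, bin_size: int = BIN_BP) -> list[GenomicInterval]:
    """Tile every chromosome from 0 in fixed-size bins (last bin truncated)."""
    bins: list[GenomicInterval] = []
    for chrom in genome:
        n = genome[chrom]
        for s in range(0, n, bin_size):
            bins.append(GenomicInterval(chrom, s, min(s + bin_size, n)))
    return bins


def poisson_mark_cutoff(lam: float, p_threshold: float) -> int:
    """Minimal k with P(Poisson(lam) >= k) <= p_threshold."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return 1
    # sf(k-1) = P(X >= k); isf gives smallest k-1 with sf <= p
    k = int(stats.poisson.isf(p_threshold, lam)) + 1
    while k > 1 and stats.poisson.sf(k - 2, lam) <= p_threshold:
        k -= 1
    while stats.poisson.sf(k - 1, lam) > p_threshold:
        k += 1
    return k


def binarize_mark(
    track: ReadTrack,
    genome: GenomeTable,
    bin_size: int = BIN_BP,
    p_threshold: float = 1.0e-4,
) -> np.ndarray:
    """Per-bin {0,1} marks by the global-Poisson upper-tail rule."""
    per_chrom = []
    for chrom in genome:
        n = genome[chrom]
        starts = np.arange(0, n, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, n)
        per_chrom.append(count_reads_arrays(track, chrom, starts, ends, mode="overlap"))
    counts = np.concatenate(per_chrom)
    if counts.sum() == 0:
        warnings.warn(
            f"track {track.cell_type}/{track.assay} has no reads; all bins unmarked",
            stacklevel=2,
        )
        return np.zeros(len(counts), dtype=np.int8)
    lam = counts.mean()
    kstar = poisson_mark_cutoff(lam, p_threshold)
    return (counts >= kstar).astype(np.int8)


@dataclass
class ChromatinStateMap:
    """Per-bin 4-state labels for one cell type on a fixed genome-wide bin grid."""

    cell_type: str
    genome: GenomeTable
    bin_size: int
    codes: np.ndarray  # int8 in {0,1,2,3}

    def __post_init__(self) -> None:
        expected = sum(-(-self.genome[c] // self.bin_size) for c in self.genome)
        if len(self.codes) != expected:
            raise ValueError("state vector length does not match the bin grid")

    @property
    def labels(self) -> np.ndarray:
        return np.array([_CODE_TO_LABEL[c] for c in self.codes.tolist()])

    def fractions(self) -> pd.Series:
        """Genome fraction of each state (sums to 1 exactly)."""
        n = len(self.codes)
        return pd.Series(
            {lab: np.sum(self.codes == code) / n for code, lab in _CODE_TO_LABEL.items()},
            name=self.cell_type,
        ).reindex(list(STATE_LABELS))

    def bins(self) -> list[GenomicInterval]:
        return genome_bins(self.genome, self.bin_size)

    def _chrom_offset(self, chrom: str) -> int:
        off = 0
        for c in self.genome:
            if c == chrom:
                return off
            off += -(-self.genome[c] // self.bin_size)
        raise KeyError(chrom)

    def codes_for_interval(self, chrom: str, start: int, end: int) -> np.ndarray:
        """State codes of the bins overlapping [start, end) on one chromosome."""
        off = self._chrom_offset(chrom)
        first = start // self.bin_size
        last = (end - 1) // self.bin_size
        n_bins = -(-self.genome[chrom] // self.bin_size)
        first, last = max(first, 0), min(last, n_bins - 1)
        return self.codes[off + first : off + last + 1]

    def marked_bins(self, states: tuple[str, ...]) -> list[GenomicInterval]:
        """Bins whose state label is in ``states``."""
        wanted = {code for code, lab in _CODE_TO_LABEL.items() if lab in states}
        return [b for b, c in zip(self.bins(), self.codes.tolist()) if c in wanted]

    def write_bed(self, path) -> None:
        all_bins = self.bins()
        write_bed(all_bins, path, names=self.labels.tolist())

    def write_tsv(self, path) -> None:
        all_bins = self.bins()
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tstate\n")
            for b, lab in zip(all_bins, self.labels.tolist()):
                fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{lab}\n")


def majority_filter(codes: np.ndarray, window: int = 3) -> np.ndarray:
    """Optional HMM-like smoothing: replace a bin's state by the majority of a
    centred window when that majority is strict; ties keep the original state."""
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    half = window // 2
    out = codes.copy()
    for i in range(half, len(codes) - half):
        seg = codes[i - half : i + half + 1]
        vals, cnts = np.unique(seg, return_counts=True)
        best = cnts.max()
        if best > window // 2 and np.sum(cnts == best) == 1:
            out[i] = vals[np.argmax(cnts)]
    return out


def assign_states(
    cell_type: str,
    k9_binary: np.ndarray,
    k27_binary: np.ndarray,
    genome: GenomeTable,
    bin_size: int = BIN_BP,
    smooth: bool = False,
) -> ChromatinStateMap:
    """Combine binarised H3K9ac and H3K27me3 into the four chromatin states."""
    k9 = np.asarray(k9_binary, dtype=np.int8)
    k27 = np.asarray(k27_binary, dtype=np.int8)
    if k9.shape != k27.shape:
        raise ValueError("H3K9ac and H3K27me3 bin grids differ in length")
    codes = k9 + 2 * k27
    if smooth:
        codes = majority_filter(codes)
    return ChromatinStateMap(cell_type, genome, bin_size, codes)


def state_map_from_tracks(
    k9_track: ReadTrack,
    k27_track: ReadTrack,
    genome: GenomeTable,
    bin_size: int = BIN_BP,
    p_threshold: float = 1.0e-4,
    smooth: bool = False,
) -> ChromatinStateMap:
    if k9_track.assay != "h3k9ac" or k27_track.assay != "h3k27me3":
        raise ValueError("expected an h3k9ac and an h3k27me3 track, in that order")
    k9 = binarize_mark(k9_track, genome, bin_size, p_threshold)
    k27 = binarize_mark(k27_track, genome, bin_size, p_threshold)
    return assign_states(k9_track.cell_type, k9, k27, genome, bin_size, smooth=smooth)


@dataclass
class StateFlow:
    """4x4 bin-count contingency of states from a source to a target cell type."""

    source: str
    target: str
    matrix: pd.DataFrame  # rows: source state, cols: target state
    source_fractions: pd.Series
    target_fractions: pd.Series

    @property
    def total_bins(self) -> int:
        return int(self.matrix.values.sum())

    def transition_fraction(self, from_state: str, to_state: str) -> float:
        """Fraction of source-state bins that end in to_state."""
        row = self.matrix.loc[from_state]
        total = row.sum()
        if total == 0:
            return float("nan")
        return float(row[to_state] / total)

    def write_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


def state_flow(map_a: ChromatinStateMap, map_b: ChromatinStateMap) -> StateFlow:
    """Alluvial contingency between two cell types on the same bin grid."""
    if len(map_a.codes) != len(map_b.codes) or map_a.bin_size != map_b.bin_size:
        raise ValueError("state maps are on different bin grids")
    mat = np.zeros((4, 4), dtype=np.int64)
    np.add.at(mat, (map_a.codes.astype(np.int64), map_b.codes.astype(np.int64)), 1)
    order = [1, 2, 3, 0]  # H3K9ac+, H3K27me3+, both, unmarked
    df = pd.DataFrame(
        mat[np.ix_(order, order)], index=list(STATE_LABELS), columns=list(STATE_LABELS)
    )
    return StateFlow(
        map_a.cell_type, map_b.cell_type, df, map_a.fractions(), map_b.fractions()
    )
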