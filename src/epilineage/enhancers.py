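"""Enhancer calling from H3K4me1, target-gene assignment, cell-type-specific
H3K9ac+ enhancer sets, and gene-set enrichment.

Enhancers are called per cell type by a Poisson sliding-window scan: 1 kb
windows at 100 bp steps are overlap-counted, tested against the genome-wide
mean window count (upper-tail Poisson), Benjamini-Hochberg adjusted across
all windows, and significant windows (q < 0.001) merged when overlapping or
adjacent. Merged peak boundaries are then refined to the outermost 100 bp
step whose count exceeds twice the background step expectation, so a peak
tracks the enriched interval rather than the full reach of its windows.
Peaks overlapping any promoter are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    GenomicInterval,
    GenomeTable,
    GeneModel,
    ReadTrack,
    count_reads,
    count_reads_arrays,
    write_bed,
)


@dataclass
class Enhancer:
    interval: GenomicInterval
    count: int
    pvalue: float
    qvalue: float

    @property
    def name(self) -> str:
        return str(self.interval)


@dataclass
class EnhancerSet:
    """Non-overlapping called enhancers of one cell type (promoter-excluded)."""

    cell_type: str
    enhancers: list[Enhancer]

    def __len__(self) -> int:
        return len(self.enhancers)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [e.interval for e in self.enhancers]

    def write_bed(self, path) -> None:
        scores = [
            min(1000.0, -np.log10(max(e.qvalue, 1e-300))) for e in self.enhancers
        ]
        write_bed(
            self.intervals, path, names=[e.name for e in self.enhancers], scores=scores
        )


def _merge_intervals(
    intervals: list[tuple[str, int, int]], adjacency: bool = True
) -> list[tuple[str, int, int, list[int]]]:
    """Merge overlapping (or adjacent) intervals; returns member indices per merge."""
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    merged: list[tuple[str, int, int, list[int]]] = []
    for i in order:
        chrom, s, e = intervals[i]
        if merged:
            mc, ms, me, members = merged[-1]
            joined = chrom == mc and (s <= me if adjacency else s < me)
            if joined:
                merged[-1] = (mc, ms, max(me, e), members + [i])
                continue
        merged.append((chrom, s, e, [i]))
    return merged


def call_enhancers(
    track: ReadTrack,
    genome: GenomeTable,
    promoters: list[GenomicInterval],
    window: int = 1000,
    step: int = 100,
    fdr: float = 0.001,
    refine_fold: float = 3.0,
) -> EnhancerSet:
    """H3K4me1 peak calling by Poisson-tested sliding windows (see module docs)."""
    if track.assay != "h3k4me1":
        raise ValueError(f"expected an h3k4me1 track, got {track.assay!r}")
    if window <= 0 or step <= 0 or window < step:
        raise ValueError("require window >= step > 0")
    win_chrom: list[str] = []
    win_starts: list[np.ndarray] = []
    win_ends: list[np.ndarray] = []
    per_chrom_counts: list[np.ndarray] = []
    for chrom in genome:
        n = genome[chrom]
        starts = np.arange(0, max(n - window, 0) + 1, step, dtype=np.int64)
        ends = np.minimum(starts + window, n)
        win_chrom.append(chrom)
        win_starts.append(starts)
        win_ends.append(ends)
        per_chrom_counts.append(
            count_reads_arrays(track, chrom, starts, ends, mode="overlap")
        )
    counts = np.concatenate(per_chrom_counts)
    lam = counts.mean() if len(counts) else 0.0
    if lam == 0:
        return EnhancerSet(track.cell_type, [])
    pvals = stats.poisson.sf(counts - 1, lam)
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    sig = np.flatnonzero(reject & (qvals < fdr))
    if sig.size == 0:
        return EnhancerSet(track.cell_type, [])
    all_starts = np.concatenate(win_starts)
    all_ends = np.concatenate(win_ends)
    chrom_of = np.repeat(win_chrom, [len(s) for s in win_starts])
    merged = _merge_intervals(
        [(chrom_of[i], int(all_starts[i]), int(all_ends[i])) for i in sig]
    )
    # empirical background at substep resolution (overlap counting inflates
    # a substep's expectation by the mean read length, so measure it)
    sub_counts = []
    for chrom in genome:
        n = genome[chrom]
        s_arr = np.arange(0, n, step, dtype=np.int64)
        e_arr = np.minimum(s_arr + step, n)
        sub_counts.append(count_reads_arrays(track, chrom, s_arr, e_arr, "overlap"))
    lam_step = float(np.concatenate(sub_counts).mean())
    enhancers: list[Enhancer] = []
    for chrom, s, e, members in merged:
        rs, re = _refine_boundaries(track, chrom, s, e, step, lam_step, refine_fold)
        iv = GenomicInterval(chrom, rs, re)
        if any(iv.overlaps(p) for p in promoters):
            continue
        member_idx = [sig[i] for i in members]
        q = float(min(qvals[i] for i in member_idx))
        p = float(min(pvals[i] for i in member_idx))
        c = int(count_reads(track, [iv], mode="overlap")[0])
        enhancers.append(Enhancer(iv, c, p, q))
    return EnhancerSet(track.cell_type, enhancers)


def _refine_boundaries(
    track: ReadTrack,
    chrom: str,
    start: int,
    end: int,
    step: int,
    lam_step: float,
    fold: float,
) -> tuple[int, int]:
    """Trim a merged peak to the outermost sub-steps enriched over background.

    Falls back to the untrimmed span when no substep clears the enrichment
    threshold (a peak significant only at window scale)."""
    edges = np.arange(start, end + step, step, dtype=np.int64)
    edges[-1] = min(edges[-1], end)
    if len(edges) < 2:
        return start, end
    sub_s, sub_e = edges[:-1], edges[1:]
    keep = sub_e > sub_s
    sub_s, sub_e = sub_s[keep], sub_e[keep]
    c = count_reads_arrays(track, chrom, sub_s, sub_e, mode="overlap")
    thresh = max(fold * lam_step, 2.0)
    hot = np.flatnonzero(c >= thresh)
    if hot.size == 0:
        return start, end
    return int(sub_s[hot[0]]), int(sub_e[hot[-1]])


def consensus_enhancers(sets: list[EnhancerSet]) -> list[GenomicInterval]:
    """Merged union of per-cell-type enhancer calls: the shared row universe."""
    all_iv = [(e.chrom, e.start, e.end) for s in sets for e in s.intervals]
    if not all_iv:
        raise ValueError("no enhancers called in any cell type")
    merged = _merge_intervals(all_iv, adjacency=False)
    return [GenomicInterval(c, s, e) for c, s, e, _ in merged]


@dataclass
class TargetAssignment:
    """Nearest-TSS target per enhancer, within 10 kb of the proximal border."""

    table: pd.DataFrame  # index: enhancer name; columns: target, distance, assigned

    def targets_of(self, enhancer_names: list[str]) -> list[str]:
        sub = self.table.loc[enhancer_names]
        return sorted(set(sub.loc[sub["assigned"], "target"]))


def assign_targets(
    enhancers: list[GenomicInterval] | EnhancerSet,
    genes: list[GeneModel],
    max_distance: int = 10_000,
) -> TargetAssignment:
    """Assign each enhancer its nearest-TSS gene; distance is measured from the
    proximal enhancer border (0 when the TSS lies inside); ties break by
    smaller gene_id; beyond ``max_distance`` the enhancer is unassigned."""
    if isinstance(enhancers, EnhancerSet):
        enhancers = enhancers.intervals
    rows = []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)
    for iv in enhancers:
        best: tuple[int, str] | None = None
        for g in genes_by_chrom.get(iv.chrom, []):
            if iv.start <= g.tss < iv.end:
                d = 0
            else:
                # distance from the nearer interval boundary
                d = min(abs(iv.start - g.tss), abs(iv.end - g.tss))
            if best is None or (d, g.gene_id) < best:
                best = (d, g.gene_id)
        if best is not None and best[0] <= max_distance:
            rows.append((str(iv), best[1], best[0], True))
        else:
            rows.append((str(iv), "", -1, False))
    df = pd.DataFrame(
        rows, columns=["enhancer", "target", "distance", "assigned"]
    ).set_index("enhancer")
    return TargetAssignment(df)


def h3k9ac_positive(enhancers: EnhancerSet, state_map) -> list[bool]:
    """Whether each enhancer overlaps >=1 H3K9ac-marked (H3K9ac+ or both) bin."""
    flags = []
    for iv in enhancers.intervals:
        codes = state_map.codes_for_interval(iv.chrom, iv.start, iv.end)
        flags.append(bool(np.any((codes == 1) | (codes == 3))))
    return flags


def specific_h3k9ac_enhancers(
    set_a: EnhancerSet,
    pos_a: list[bool],
    set_b: EnhancerSet,
    pos_b: list[bool],
) -> dict[str, list[GenomicInterval]]:
    """Split H3K9ac+ enhancers of two cell types into A-specific / B-specific /
    shared by >=1 bp genomic overlap between the marked enhancers."""
    a_pos = [iv for iv, f in zip(set_a.intervals, pos_a) if f]
    b_pos = [iv for iv, f in zip(set_b.intervals, pos_b) if f]
    a_specific, shared_a = [], []
    for iv in a_pos:
        if any(iv.overlaps(o) for o in b_pos):
            shared_a.append(iv)
        else:
            a_specific.append(iv)
    b_specific = [iv for iv in b_pos if not any(iv.overlaps(o) for o in a_pos)]
    shared_b = [iv for iv in b_pos if any(iv.overlaps(o) for o in a_pos)]
    return {
        "a_specific": a_specific,
        "b_specific": b_specific,
        "shared": shared_a + [iv for iv in shared_b if not any(iv.overlaps(o) for o in shared_a)],
    }


# ---------------------------------------------------------------------------
# Gene-set enrichment (hypergeometric, user-supplied GMT sets)
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Standard GMT: set name, description, then member genes, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: GMT lines need name, description, members")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description] + list(members)) + "\n")


def gene_set_enrichment(
    query: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    top_n: int = 5,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a query against each set,
    BH-adjusted across sets, sorted by p; the best ``top_n`` are flagged."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    if not q <= uni:
        raise ValueError("query genes must be contained in the universe")
    rows = []
    for name, members in gene_sets.items():
        m = set(members) & uni
        overlap = len(q & m)
        # P(X >= overlap), X ~ Hypergeom(M=|uni|, K=|m|, n=|q|)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(m), len(q)))
        rows.append((name, len(m), overlap, p))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "pvalue"])
    if len(df):
        _, qv, _, _ = multipletests(df["pvalue"].values, method="fdr_bh")
        df["qvalue"] = qv
        df = df.sort_values(["pvalue", "set"], kind="stable").reset_index(drop=True)
        df["top"] = [i < top_n for i in range(len(df))]
    return df
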