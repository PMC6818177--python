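"""RPM histone-mark signal over promoters and enhancers.

Promoters are the strand-symmetric windows [TSS-1kb, TSS+1kb), clipped at
chromosome ends; no orientation flip is needed. Enhancer columns are
quantified over a single consensus universe (the merged union of per-cell
calls) so all cell types share a row space. Reads are overlap-counted and
RPM-normalised by the track's total mapped count.
"""

from __future__ import annotations

import numpy as np

from .core import (
    GeneModel,
    GenomeTable,
    GenomicInterval,
    ReadTrack,
    SignalMatrix,
    count_reads,
    rpm_normalize,
)

PROMOTER_FLANK = 1000


def promoter_regions(
    genes: list[GeneModel], genome: GenomeTable | None = None, flank: int = PROMOTER_FLANK
) -> list[GenomicInterval]:
    """[TSS-flank, TSS+flank) per gene, clipped to chromosome bounds."""
    out = []
    for g in genes:
        chrom = g.interval.chrom
        start = max(g.tss - flank, 0)
        end = g.tss + flank
        if genome is not None:
            end = min(end, genome[chrom])
        out.append(GenomicInterval(chrom, start, end))
    return out


def _require_hm(track: ReadTrack) -> None:
    if track.assay not in ("h3k9ac", "h3k27me3"):
        raise ValueError(
            f"expected an H3K9ac or H3K27me3 track, got {track.assay!r}"
        )


def promoter_signal(
    track: ReadTrack, promoters: list[GenomicInterval]
) -> np.ndarray:
    """Overlap-counted RPM per promoter for one HM track."""
    _require_hm(track)
    counts = count_reads(track, promoters, mode="overlap")
    return rpm_normalize(counts, track.total_mapped)


def enhancer_signal(
    track: ReadTrack, consensus: list[GenomicInterval]
) -> np.ndarray:
    """Overlap-counted RPM per consensus enhancer for one HM track."""
    _require_hm(track)
    if not consensus:
        raise ValueError("empty consensus enhancer universe")
    counts = count_reads(track, consensus, mode="overlap")
    return rpm_normalize(counts, track.total_mapped)


def signal_matrix(
    tracks: list[ReadTrack],
    regions: list[GenomicInterval],
    row_ids: list[str] | None = None,
) -> SignalMatrix:
    """Regions x cell types RPM matrix from one HM assay's tracks."""
    assays = {t.assay for t in tracks}
    if len(assays) != 1:
        raise ValueError("all tracks must share one assay")
    if not regions:
        raise ValueError("empty region universe")
    if row_ids is None:
        row_ids = [str(r) for r in regions]
    cols = [promoter_signal(t, regions) for t in tracks]
    return SignalMatrix(
        row_ids, [t.cell_type for t in tracks], np.column_stack(cols), units="RPM"
    )
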