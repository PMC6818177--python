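"""Expression quantification (RPKM), differential-expression calls, and the
DEG-restricted expression matrix used for clustering.

Differential expression between two libraries (one sample per cell type, no
replicates) is tested with an exact conditional binomial rate test: given a
gene's pooled count n = cA + cB, cA ~ Binomial(n, NA/(NA+NB)) under the null
that both libraries sample the gene at the same rate, where NA and NB are
the library totals. Two-sided p-values are twice the smaller tail, capped at
1, and are Benjamini-Hochberg adjusted across genes; a gene is a DEG when
q < fdr (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import SignalMatrix


@dataclass
class ExpressionTable:
    """Raw counts and RPKM per gene x cell type."""

    counts: pd.DataFrame  # genes x cell types, integer counts
    rpkm_values: pd.DataFrame  # same shape, RPKM
    lengths_kb: pd.Series  # per-gene transcript length (kb)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.counts.columns)

    def library_total(self, cell: str) -> int:
        return int(self.counts[cell].sum())

    @classmethod
    def from_counts(
        cls, counts: pd.DataFrame, lengths_kb: pd.Series
    ) -> "ExpressionTable":
        if (counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        lengths_kb = lengths_kb.reindex(counts.index)
        if lengths_kb.isna().any():
            raise ValueError("missing gene length for some genes")
        totals = counts.sum(axis=0)
        rpkm_values = counts.div(lengths_kb, axis=0).div(totals / 1.0e6, axis=1)
        return cls(counts, rpkm_values, lengths_kb)

    def rpkm_matrix(self) -> SignalMatrix:
        return SignalMatrix(
            self.gene_ids, self.cell_types, self.rpkm_values.values, units="RPKM"
        )


@dataclass
class DEGResult:
    """Per-gene test results for one cell-type pair."""

    cell_a: str
    cell_b: str
    table: pd.DataFrame  # columns: log2fc, pvalue, qvalue, is_deg
    fdr: float

    @property
    def deg_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_deg"]])


def rpkm(count, length_kb, total_mapped) -> np.ndarray | float:
    """Reads per kilobase per million mapped reads."""
    length_kb = np.asarray(length_kb, dtype=float)
    if np.any(length_kb <= 0):
        raise ValueError("length_kb must be > 0")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    out = np.asarray(count, dtype=float) / (length_kb * (total_mapped / 1.0e6))
    return out if out.ndim else float(out)


def _binomial_two_sided(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    """Vectorised two-sided exact binomial p (twice the smaller tail, capped at 1)."""
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    pvals = 2.0 * np.minimum(lower, upper)
    pvals[n == 0] = 1.0
    return np.minimum(pvals, 1.0)


def call_degs(
    table: ExpressionTable,
    pair: tuple[str, str],
    fdr: float = 0.05,
    pseudo: float = 1.0,
) -> DEGResult:
    """Exact conditional binomial DEG test for one cell-type pair.

    Genes with zero counts in both libraries get p = 1 and remain in the BH
    family. The pseudocount enters only the reported fold change
    (log2((cA/NA + p0)/(cB/NB + p0)) with p0 = pseudo/min(NA, NB)), never
    the test.
    """
    cell_a, cell_b = pair
    for c in pair:
        if c not in table.cell_types:
            raise KeyError(f"cell type {c!r} not in expression table")
    ca = table.counts[cell_a].to_numpy(dtype=np.int64)
    cb = table.counts[cell_b].to_numpy(dtype=np.int64)
    na, nb = table.library_total(cell_a), table.library_total(cell_b)
    if na <= 0 or nb <= 0:
        raise ValueError("library totals must be positive")
    p_null = na / (na + nb)
    pvals = _binomial_two_sided(ca, ca + cb, p_null)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    p0 = pseudo / min(na, nb)
    log2fc = np.log2((ca / na + p0) / (cb / nb + p0))
    df = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
            "is_deg": qvals < fdr,
        },
        index=table.counts.index,
    )
    return DEGResult(cell_a, cell_b, df, fdr)


def call_degs_all_pairs(
    table: ExpressionTable, fdr: float = 0.05, pseudo: float = 1.0
) -> list[DEGResult]:
    cells = table.cell_types
    return [
        call_degs(table, (cells[i], cells[j]), fdr=fdr, pseudo=pseudo)
        for i in range(len(cells))
        for j in range(i + 1, len(cells))
    ]


def deg_union_matrix(
    table: ExpressionTable, deg_results: list[DEGResult], log2: bool = False
) -> SignalMatrix:
    """RPKM matrix restricted to the union of DEGs over all pairwise tests.

    ``log2`` applies log2(RPKM + 1) before returning; clustering downstream
    Z-scores per gene either way, so this mainly tempers heavy tails.
    """
    if len(table.cell_types) < 2:
        raise ValueError("need >= 2 cell types")
    union: set[str] = set()
    for res in deg_results:
        union.update(res.deg_genes)
    if not union:
        raise ValueError(
            "no gene is differentially expressed in any pair; "
            "consider relaxing the FDR threshold"
        )
    keep = [g for g in table.gene_ids if g in union]
    values = table.rpkm_values.loc[keep].values
    if log2:
        values = np.log2(values + 1.0)
    return SignalMatrix(keep, table.cell_types, values, units="RPKM")


def write_deg_report(results: list[DEGResult], path) -> None:
    frames = []
    for res in results:
        df = res.table.copy()
        df.insert(0, "pair", f"{res.cell_a}_vs_{res.cell_b}")
        df.insert(0, "gene_id", df.index)
        frames.append(df)
    pd.concat(frames, axis=0).to_csv(path, sep="\t", index=False)
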