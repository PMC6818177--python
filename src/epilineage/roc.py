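"""ROC evaluation of histone-mark signal as a predictor of gene activity.

Gene-activity labels follow a top-k / bottom-k convention: the k most (or
least) expressed genes are the actual positives, the rest the negatives
(boundary ties broken by gene_id so exactly k genes are positive). The ROC
curve uses every distinct signal value as a threshold with a >= decision
rule; the AUC is the trapezoid area over the (FPR, TPR) polyline, which
equals the pairwise statistic P(signal_pos > signal_neg) + 0.5 P(tie).

For the active mark H3K9ac the top-k convention applies; for the repressive
mark H3K27me3, low expression is the positive class (bottom-k) since high
signal is expected on silent genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SignalMatrix
from .enhancers import TargetAssignment


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending distinct signal values
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    convention: str  # top_k_positives | bottom_k_positives
    k: int

    def points_frame(self) -> pd.DataFrame:
        thr = np.concatenate(([np.inf], self.thresholds))
        return pd.DataFrame({"threshold": thr, "fpr": self.fpr, "tpr": self.tpr})


def label_genes(
    expression: pd.Series, convention: str, k: int = 1500
) -> pd.Series:
    """Boolean positive labels for the k highest (top_k_positives) or lowest
    (bottom_k_positives) expressed genes; ties at the boundary break by gene_id."""
    if convention not in ("top_k_positives", "bottom_k_positives"):
        raise ValueError(f"unknown convention {convention!r}")
    n = len(expression)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    sign = -1.0 if convention == "top_k_positives" else 1.0
    order = sorted(expression.index, key=lambda g: (sign * expression[g], g))
    positives = set(order[:k])
    return pd.Series(
        [g in positives for g in expression.index], index=expression.index
    )


def roc(signal: np.ndarray | pd.Series, labels: np.ndarray | pd.Series) -> ROCCurve:
    """ROC curve and trapezoid AUC of a signal against boolean labels."""
    signal = np.asarray(signal, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if signal.shape != labels.shape:
        raise ValueError("signal and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    order = np.argsort(-signal, kind="stable")
    s_sorted = signal[order]
    l_sorted = labels[order]
    # distinct thresholds, descending
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    last_of_run = np.concatenate((boundary, [len(s_sorted) - 1]))
    thresholds = s_sorted[last_of_run]
    tp = np.cumsum(l_sorted)[last_of_run]
    fp = np.cumsum(~l_sorted)[last_of_run]
    tpr = np.concatenate(([0.0], tp / n_pos))
    fpr = np.concatenate(([0.0], fp / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    convention = "top_k_positives"
    return ROCCurve(thresholds, tpr, fpr, auc, convention, n_pos)


def roc_for_genes(
    signal: pd.Series, expression: pd.Series, convention: str, k: int,
    cap_k: bool = False,
) -> ROCCurve:
    """Label genes by expression, align the signal, and build the ROC.

    ``cap_k`` caps k below the shared gene count (used for enhancer-mapped
    signal, where genes without enhancers shrink the universe); without it,
    an oversized k is an error.
    """
    common = signal.index.intersection(expression.index)
    if len(common) == 0:
        raise ValueError("no genes shared between signal and expression")
    expr = expression.loc[common]
    k_eff = min(k, len(common) - 1) if cap_k else k
    labels = label_genes(expr, convention, k=k_eff)
    curve = roc(signal.loc[common].values, labels.values)
    curve.convention = convention
    return curve


def enhancer_signal_by_gene(
    matrix: SignalMatrix, targets: TargetAssignment, cell: str
) -> pd.Series:
    """Map a consensus-enhancer signal column onto target genes, taking the
    max over a gene's enhancers; genes without an assigned enhancer are absent."""
    col = pd.Series(matrix.col(cell), index=matrix.row_ids)
    tab = targets.table
    assigned = tab[tab["assigned"]]
    values: dict[str, float] = {}
    for enh, row in assigned.iterrows():
        v = col.get(enh)
        if v is None:
            continue
        g = row["target"]
        values[g] = max(values.get(g, -np.inf), float(v))
    return pd.Series(values).sort_index()


def roc_suite(
    promoter_matrices: dict[str, SignalMatrix],
    expression_rpkm: pd.DataFrame,
    k: int = 1500,
    enhancer_matrices: dict[str, SignalMatrix] | None = None,
    targets: TargetAssignment | None = None,
) -> pd.DataFrame:
    """AUC table over (mark, element class, cell type).

    ``promoter_matrices``/``enhancer_matrices`` map assay name ->
    genes-or-enhancers x cells RPM matrix. H3K9ac uses the top-k convention,
    H3K27me3 the bottom-k one. Enhancer signal reaches genes through target
    assignment; k is capped below each evaluation's class sizes.
    """
    conventions = {"h3k9ac": "top_k_positives", "h3k27me3": "bottom_k_positives"}
    rows = []
    curves: dict[tuple[str, str, str], ROCCurve] = {}
    for assay, matrix in promoter_matrices.items():
        for cell in matrix.col_ids:
            sig = pd.Series(matrix.col(cell), index=matrix.row_ids)
            expr = expression_rpkm[cell]
            curve = roc_for_genes(sig, expr, conventions[assay], k)
            curves[(assay, "promoter", cell)] = curve
            rows.append((assay, "promoter", cell, curve.convention, curve.k, curve.auc))
    if enhancer_matrices:
        if targets is None:
            raise ValueError("enhancer evaluation requires target assignments")
        for assay, matrix in enhancer_matrices.items():
            for cell in matrix.col_ids:
                sig = enhancer_signal_by_gene(matrix, targets, cell)
                expr = expression_rpkm[cell]
                curve = roc_for_genes(sig, expr, conventions[assay], k, cap_k=True)
                curves[(assay, "enhancer", cell)] = curve
                rows.append(
                    (assay, "enhancer", cell, curve.convention, curve.k, curve.auc)
                )
    df = pd.DataFrame(
        rows, columns=["mark", "element", "cell", "convention", "k", "auc"]
    )
    df.attrs["curves"] = curves
    return df
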