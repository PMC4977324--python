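"""Scoring of holdout outputs.

Three views are produced: ROC curves with trapezoidal AUC for the two
posterior score vectors against the true labels; a two-sample
Kolmogorov-Smirnov test comparing the distribution of the
transcription-complex predictions with that of the tissue-status
predictions (the study's central question is whether those two
distributions coincide); and per-gene conditional summaries of the mean
complex posterior grouped by each gene's evidence state within each true
class, with a majority-state "inferred relation" per gene and class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics

from .holdout import HoldoutResult
from .synthetic import ExpressionDataset

__all__ = [
    "RocCurve",
    "KsResult",
    "compute_roc",
    "ks_two_sample",
    "summarize_gene_trcmplx",
]


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


@dataclass(frozen=True)
class KsResult:
    statistic: float
    pvalue: float
    alpha: float
    h01: int  # 1 iff the two distributions differ at level alpha

    def __post_init__(self) -> None:
        if not 0.0 <= self.statistic <= 1.0:
            raise ValueError("KS statistic must lie in [0, 1]")


def compute_roc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """Threshold-sweep ROC with trapezoidal AUC; ties share a threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D vectors of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("labels must be -1 or +1")
    if np.unique(y).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = metrics.roc_curve(y, s, pos_label=1)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(metrics.auc(fpr, tpr)))


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> KsResult:
    """Two-sample KS test: D = sup |ECDF_x - ECDF_y|, asymptotic p-value
    (effective-n corrected), rejection flag at level ``alpha``."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size == 0 or yv.size == 0:
        raise ValueError("both samples must be nonempty")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    res = stats.ks_2samp(xv, yv, method="asymp")
    h01 = int(res.pvalue < alpha)
    return KsResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue), alpha=alpha, h01=h01
    )


def summarize_gene_trcmplx(
    results: Sequence[HoldoutResult],
    dataset: ExpressionDataset | None = None,
) -> pd.DataFrame:
    """Mean Pr(TRCMPLX=active) per gene, evidence state and true class.

    For each gene and class, test samples are grouped by the gene's
    evidence state; the majority state (ties break toward repressed,
    state 1) selects the "inferred belief" — the mean complex posterior
    under the majority evidence. A class never observed in some state is
    reported with count 0 and an empty mean rather than NaN propagation.
    """
    if not results:
        raise ValueError("no holdout results to summarize")
    genes = sorted({g for r in results for g in r.evidence})
    if dataset is not None:
        # report rows in the dataset's gene order
        genes = [g for g in dataset.genes if g in set(genes)]
    rows = []
    for gene in genes:
        for cls, cls_name in ((-1, "normal"), (1, "tumor")):
            group = [r for r in results if r.true_label == cls]
            state1 = [r.p_trcmplx for r in group if r.evidence.get(gene) == 1]
            state2 = [r.p_trcmplx for r in group if r.evidence.get(gene) == 2]
            n1, n2 = len(state1), len(state2)
            majority = 1 if n1 >= n2 else 2  # tie -> repressed
            chosen = state1 if majority == 1 else state2
            rows.append(
                {
                    "gene": gene,
                    "true_class": cls_name,
                    "n_repressed": n1,
                    "mean_p_trcmplx_repressed": float(np.mean(state1)) if n1 else None,
                    "n_active": n2,
                    "mean_p_trcmplx_active": float(np.mean(state2)) if n2 else None,
                    "majority_state": "repressed" if majority == 1 else "active",
                    "inferred_belief": float(np.mean(chosen)) if chosen else None,
                    "no_evidence": n1 + n2 == 0,
                }
            )
    return pd.DataFrame(rows)
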