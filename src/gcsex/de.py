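"""Two-group differential expression and Pearson correlation testing.

Differential expression uses per-gene Welch two-sample t tests on log2
expression with Benjamini-Hochberg adjustment across genes; the log2 fold
change is the difference of group means (group2 - group1). The screening
filter keeps genes with p below a threshold and fold change above one; by
default the fold-change threshold is read on the log2 scale (|log2FC| >
0.5), with a linear-scale variant available.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix


def group_de(matrix: ExpressionMatrix, labels: list[str]) -> pd.DataFrame:
    """Welch-t differential expression between two groups.

    ``labels`` assigns each sample to one of exactly two groups; logFC is
    mean(group2) - mean(group1) with groups in sorted label order. Returns
    a DataFrame indexed by gene with columns log_fc, t, p, p_adj.
    """
    if len(labels) != matrix.n_samples:
        raise ValueError("labels do not align with samples")
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    m1 = np.asarray([l == groups[0] for l in labels])
    m2 = ~m1
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    X1, X2 = matrix.values[:, m1], matrix.values[:, m2]
    t, p = stats.ttest_ind(X2, X1, axis=1, equal_var=False)
    log_fc = X2.mean(axis=1) - X1.mean(axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log_fc": log_fc, "t": t, "p": p, "p_adj": p_adj},
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def deg_filter(table: pd.DataFrame, p_thresh: float = 0.05,
               lfc_thresh: float = 0.5, scale: str = "log2") -> list[str]:
    """Genes passing the significance + fold-change screen.

    Strict inequalities: p < p_thresh and |log2FC| > lfc_thresh (default)
    or linear fold change 2**log_fc > lfc_thresh with ``scale='linear'``.
    """
    if p_thresh <= 0 or lfc_thresh < 0:
        raise ValueError("thresholds must be positive")
    if scale == "log2":
        keep = (table["p"] < p_thresh) & (table["log_fc"].abs() > lfc_thresh)
    elif scale == "linear":
        keep = (table["p"] < p_thresh) & (2.0 ** table["log_fc"] > lfc_thresh)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return list(table.index[keep])


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-approximation p value.

    p is computed from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom. Requires length >= 3 and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector has no defined correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
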