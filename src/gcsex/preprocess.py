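"""Expression preprocessing: CPM log-normalization, per-gene z-scaling,
train/validation splitting and the 2^-ddCt qPCR helper.

The classifier pipeline is: counts -> log2(CPM + pseudocount) -> per-gene
standardization (subtract the gene mean, divide by the gene sd) ->
train/validation split. Scaling statistics are fit on the training samples
only by default to avoid information leakage into validation; a
scale-all-first variant is available for parity with workflows that
standardize the full matrix before splitting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import train_test_split

from .datatypes import ExpressionMatrix, ScaledMatrix


def cpm_log_normalize(counts: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + pseudocount) per sample.

    Each sample column is scaled to a library size of 1e6 before the log
    step. Requires a counts-scale matrix with positive column sums.
    """
    if counts.scale != "counts":
        raise ValueError(f"expected a counts-scale matrix, got scale={counts.scale!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    colsums = counts.values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise ValueError(
            f"all-zero sample column(s): {[counts.sample_ids[i] for i in zero]}"
        )
    cpm = counts.values / colsums * 1e6
    return ExpressionMatrix(
        values=np.log2(cpm + pseudocount),
        gene_ids=counts.gene_ids,
        sample_ids=counts.sample_ids,
        scale="log2",
    )


class GeneZScaler(TransformerMixin, BaseEstimator):
    """Standardize each gene across samples; drop zero-variance genes.

    Follows the sklearn transformer protocol on (n_samples, n_genes)
    arrays: ``fit`` learns per-gene means and sds, ``transform`` applies
    them and removes the columns recorded in ``dropped_idx_``. Population
    sd (ddof=0) is used.
    """

    def __init__(self, atol: float = 0.0):
        self.atol = atol

    def fit(self, X: np.ndarray, y=None) -> "GeneZScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2D array with >= 2 samples")
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0, ddof=0)
        self.dropped_idx_ = np.flatnonzero(self.sds_ <= self.atol)
        self.kept_idx_ = np.flatnonzero(self.sds_ > self.atol)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        Z = (X[:, self.kept_idx_] - self.means_[self.kept_idx_]) / self.sds_[self.kept_idx_]
        return Z


def zscale_genes(matrix: ExpressionMatrix) -> ScaledMatrix:
    """Per-gene standardization of a gene x sample matrix.

    Zero-variance genes cannot be scaled (division by sd) and are dropped,
    with their ids recorded in ``dropped_genes``.
    """
    if matrix.n_samples < 2:
        raise ValueError("z-scaling needs at least 2 samples")
    scaler = GeneZScaler().fit(matrix.samples_by_genes())
    Z = scaler.transform(matrix.samples_by_genes())
    kept = [matrix.gene_ids[i] for i in scaler.kept_idx_]
    dropped = [matrix.gene_ids[i] for i in scaler.dropped_idx_]
    return ScaledMatrix(
        values=Z.T,
        gene_ids=kept,
        sample_ids=list(matrix.sample_ids),
        gene_means=scaler.means_[scaler.kept_idx_],
        gene_sds=scaler.sds_[scaler.kept_idx_],
        dropped_genes=dropped,
    )


@dataclass
class SplitPlan:
    """A train/validation partition of the sample ids."""

    train_ids: list[str]
    validation_ids: list[str]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"train/validation overlap: {sorted(overlap)[:5]}")


def split_train_validation(
    sample_ids: list[str],
    fraction: float = 0.10,
    seed: int = 0,
    stratify_by_sex: list[str] | None = None,
) -> SplitPlan:
    """Hold out ``fraction`` of samples for validation.

    With ``stratify_by_sex`` (a per-sample sex list) the split preserves
    sex proportions; otherwise it is a plain random split.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_val = int(round(fraction * len(sample_ids)))
    if n_val < 1 or n_val >= len(sample_ids):
        raise ValueError("fraction leaves an empty train or validation set")
    train, val = train_test_split(
        list(sample_ids),
        test_size=n_val,
        random_state=seed,
        shuffle=True,
        stratify=stratify_by_sex,
    )
    return SplitPlan(train_ids=list(train), validation_ids=list(val),
                     fraction=fraction, seed=seed)


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative qPCR quantification by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator;
    the fold change is 2**(-ddCt), strictly positive for finite inputs.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))
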