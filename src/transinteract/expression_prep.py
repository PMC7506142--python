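"""Expression-matrix preprocessing: missingness filter and kNN imputation.

Matrices are samples x features (genes, RBP genes, or microRNAs). Features
missing in more than ``max_missing_fraction`` of samples are dropped
(strictly more — a feature missing in exactly 30% of samples survives the
default filter); remaining gaps are filled by k-nearest-neighbor
imputation over features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Samples x features expression values with a condition label."""

    data: pd.DataFrame  # index = sample ids, columns = feature ids
    condition_label: str = "pooled"
    sample_conditions: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("feature ids must be unique")
        if self.sample_conditions is None:
            self.sample_conditions = pd.Series(
                self.condition_label, index=self.data.index
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)


def filter_missing(
    matrix: ExpressionMatrix, max_missing_fraction: float = 0.3
) -> ExpressionMatrix:
    """Drop features whose missing fraction exceeds the cutoff (strictly)."""
    frac = matrix.data.isna().mean(axis=0)
    keep = frac[frac <= max_missing_fraction].index
    if len(keep) == 0:
        raise ValueError("missingness filter removed every feature")
    dropped = matrix.data.shape[1] - len(keep)
    if dropped:
        logger.info("filter_missing dropped %d features", dropped)
    return ExpressionMatrix(
        matrix.data[keep].copy(), matrix.condition_label,
        matrix.sample_conditions,
    )


def knn_impute(matrix: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing cells from the k nearest features.

    A missing cell (sample s, feature f) becomes the mean over the k
    features closest to f — Euclidean distance computed on co-observed
    samples and rescaled by the co-observation count — of their values at
    s. Observed cells are never altered. When fewer than k complete donors
    exist, all available ones are used (with a warning from the imputer).
    """
    if not matrix.data.isna().to_numpy().any():
        return matrix
    # KNNImputer treats rows as the units being imputed from; transposing
    # puts features in rows so neighbors are features, as intended.
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(matrix.data.to_numpy(float).T).T
    out = pd.DataFrame(filled, index=matrix.data.index, columns=matrix.data.columns)
    assert not out.isna().to_numpy().any()
    return ExpressionMatrix(out, matrix.condition_label, matrix.sample_conditions)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1), for variance stabilization before OLS."""
    if (matrix.data < 0).to_numpy().any():
        raise ValueError("log transform requires non-negative values")
    return ExpressionMatrix(
        np.log2(matrix.data + 1.0), matrix.condition_label,
        matrix.sample_conditions,
    )


def align_conditions(
    tumor: ExpressionMatrix, normal: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
    """Intersect features and build (tumor-only, normal-only, pooled).

    The pooled matrix is the row-wise concatenation over shared features;
    each sample keeps its provenance label.
    """
    shared = tumor.data.columns.intersection(normal.data.columns)
    if len(shared) == 0:
        raise ValueError("no shared features between the two conditions")
    t = ExpressionMatrix(tumor.data[shared].copy(), tumor.condition_label)
    n = ExpressionMatrix(normal.data[shared].copy(), normal.condition_label)
    pooled_data = pd.concat([t.data, n.data], axis=0)
    if pooled_data.index.duplicated().any():
        raise ValueError("tumor and normal sample ids must be disjoint")
    labels = pd.concat([
        pd.Series(tumor.condition_label, index=t.data.index),
        pd.Series(normal.condition_label, index=n.data.index),
    ])
    pooled = ExpressionMatrix(pooled_data, "pooled", labels)
    return t, n, pooled


def read_expression_tsv(path, condition_label: str = "pooled") -> ExpressionMatrix:
    """TSV with features in rows, samples in columns, NA = missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return ExpressionMatrix(df.T, condition_label)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.data.T.to_csv(path, sep="\t", na_rep="NA")
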