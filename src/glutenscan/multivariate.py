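"""Log transform, Pareto scaling and PCA of abundance matrices.

The transform pipeline follows the MetaboAnalyst convention:
missing-value imputation, then ``log10(x + pseudo)``, then per-feature
Pareto scaling — centre on the feature mean and divide by the square
root of the sample standard deviation (intermediate between unit
variance and no scaling).  Samples are observations and protein groups
(or motifs) are features.

The PCA is a plain SVD of the column-centred sample x feature matrix
with a fixed sign convention (the largest-magnitude loading of each
component is positive), so results are deterministic across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def impute_missing(matrix: pd.DataFrame, method: str = "half_min") -> pd.DataFrame:
    """Impute NaN cells per feature row.

    ``half_min``: half the smallest observed positive value of the row
    (MetaboAnalyst-like); ``zero``: 0; ``drop``: remove rows with any
    missing cell.
    """
    if method == "drop":
        return matrix.dropna(axis=0)
    out = matrix.copy()
    if method == "zero":
        return out.fillna(0.0)
    if method != "half_min":
        raise ValueError(f"unknown imputation method {method!r}")
    for idx in out.index[out.isna().any(axis=1)]:
        row = out.loc[idx]
        positive = row[row > 0]
        if positive.empty:
            out.loc[idx] = row.fillna(0.0)
        else:
            out.loc[idx] = row.fillna(positive.min() / 2.0)
    return out


def log_pareto(
    matrix: pd.DataFrame,
    pseudo: float | None = None,
    impute: str = "half_min",
) -> pd.DataFrame:
    """``log10(x + pseudo)`` then Pareto-scale each feature row.

    ``pseudo`` defaults to 1 when the matrix contains zeros, else 0.
    Rows with zero variance after the log transform are dropped with a
    warning.  Negative input values are an error.
    """
    filled = impute_missing(matrix, impute)
    vals = filled.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("abundance matrix contains negative values")
    if pseudo is None:
        pseudo = 1.0 if (vals == 0).any() else 0.0
    logged = np.log10(vals + pseudo)
    logged_df = pd.DataFrame(logged, index=filled.index, columns=filled.columns)
    means = logged_df.mean(axis=1)
    sds = logged_df.std(axis=1, ddof=1)
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} zero-variance feature row(s): "
            f"{list(logged_df.index[constant])}"
        )
    kept = logged_df.loc[~constant]
    return kept.sub(means[~constant], axis=0).div(np.sqrt(sds[~constant]), axis=0)


@dataclass
class PCAResult:
    """Scores, loadings and explained variance of a PCA.

    ``scores``: samples x components; ``loadings``: features x
    components (orthonormal columns); ``explained_variance_fraction``
    covers every component of the decomposition, so it sums to 1.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray
    column_means: pd.Series

    @property
    def cumulative_variance_fraction(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_fraction)


def pca(matrix: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """PCA of a feature x sample abundance matrix.

    Samples are treated as observations (the matrix is transposed
    internally) and mean-centred per feature.  Deterministic: the
    decomposition is a full SVD and each component is oriented so its
    largest-magnitude loading is positive.
    """
    X = matrix.T.to_numpy(dtype=float)  # samples x features
    n_samples, n_features = X.shape
    if n_samples < 2 or n_features < 2:
        raise ValueError("PCA requires at least 2 samples and 2 features")
    if n_components > min(n_samples, n_features):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_features)="
            f"{min(n_samples, n_features)}"
        )
    means = X.mean(axis=0)
    Xc = X - means
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fixed orientation: largest |loading| positive per component
    for k in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    total = float((s**2).sum())
    fractions = (s**2) / total if total > 0 else np.zeros_like(s)
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(
        (U * s)[:, :n_components], index=matrix.columns, columns=comp_names[:n_components]
    )
    loadings = pd.DataFrame(
        Vt.T[:, :n_components], index=matrix.index, columns=comp_names[:n_components]
    )
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=fractions,
        column_means=pd.Series(means, index=matrix.index),
    )
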