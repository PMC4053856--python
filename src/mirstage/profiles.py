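"""Row-standardized expression matrices and PCA of the most-variant miRNAs."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

__all__ = ["PCAResult", "row_standardize", "top_variant", "pca"]


@dataclass
class PCAResult:
    scores: pd.DataFrame       # sample x component
    loadings: pd.DataFrame     # miRNA x component
    variance_explained: pd.Series


def row_standardize(mat: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to mean 0, sample sd 1 (ddof=1).

    Constant rows carry no relative-expression signal and are dropped with a
    warning.
    """
    sd = mat.std(axis=1, ddof=1)
    const = sd.index[(sd == 0) | sd.isna()]
    if len(const):
        warnings.warn(f"dropping {len(const)} constant row(s): {list(const[:5])}...",
                      stacklevel=2)
        mat = mat.drop(index=const)
        sd = sd.drop(index=const)
    return mat.sub(mat.mean(axis=1), axis=0).div(sd, axis=0)


def top_variant(mat: pd.DataFrame, fraction: float = 0.5) -> pd.DataFrame:
    """Rows with the highest variance; ``fraction`` rounds half-down.

    581 rows at fraction 0.5 give 290 ("top half"). Ties at the cutoff break
    by id order (lexicographically earlier kept) for determinism.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = int(np.ceil(fraction * len(mat) - 0.5))
    n_keep = max(n_keep, 1)
    var = mat.var(axis=1, ddof=1)
    order = pd.DataFrame({"var": -var.to_numpy(), "id": var.index}).sort_values(
        ["var", "id"], kind="mergesort")
    keep = order["id"].iloc[:n_keep]
    return mat.loc[keep]


def pca(mat: pd.DataFrame) -> PCAResult:
    """SVD-based PCA with samples as observations and miRNAs as variables.

    Input rows are miRNAs, columns samples (as produced by row_standardize);
    the matrix is transposed internally. The sign of each component is fixed
    so its largest-magnitude loading is positive.
    """
    if mat.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    X = mat.to_numpy(dtype=float).T  # samples x miRNAs
    n_comp = min(X.shape[0] - 1, X.shape[1])
    model = _SKPCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # miRNA x component
    # deterministic sign convention
    for j in range(n_comp):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=mat.columns, columns=comps),
        loadings=pd.DataFrame(loadings, index=mat.index, columns=comps),
        variance_explained=pd.Series(model.explained_variance_ratio_, index=comps),
    )
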