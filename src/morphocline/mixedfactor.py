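"""PCA of mixed categorical + continuous data, with iterative imputation.

The mixed analysis is the PCAmix formulation: continuous columns are
standardized (population variance); each categorical column is expanded
into centered indicator columns weighted by inverse category frequency;
the concatenated matrix is decomposed by a generalized SVD with row
weights 1/n.  In the all-continuous limit this reduces to ordinary
correlation-matrix PCA, and in the all-categorical limit to multiple
correspondence analysis (eigenvalues scaled by the number of
variables).  Total inertia is ``p_cont + (total categories - number of
categorical variables)``.

Missing continuous cells are completed beforehand by iterative PCA
imputation: initialize at column means, then alternate a low-rank SVD
reconstruction of the missing cells until the imputed values stop
changing.  Observed cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MixedPCAResult", "mixed_pca", "iterative_impute_pca"]


@dataclass
class MixedPCAResult:
    eigenvalues: np.ndarray          # all positive eigenvalues, descending
    scores: pd.DataFrame             # specimens x retained axes
    loadings: pd.DataFrame           # variables/categories x retained axes
    squared_loadings: pd.DataFrame   # per original variable x axes
    proportion: np.ndarray           # inertia share per retained axis
    total_inertia: float


def mixed_pca(
    continuous: pd.DataFrame | None,
    categorical: pd.DataFrame | None,
    n_axes: int = 2,
    population_variance: bool = True,
) -> MixedPCAResult:
    """PCA of mixed data (PCAmix generalized SVD).

    ``continuous`` and ``categorical`` share row order; either may be
    ``None``/empty.  No missing values are allowed (impute first; a
    categorical missing level should be made explicit by the caller).
    Axis signs are fixed so the variable with the largest absolute
    loading on each axis is positive.
    """
    blocks = []
    col_weights = []
    col_names = []
    var_of_col = []

    if continuous is not None and continuous.shape[1]:
        if continuous.isna().any().any():
            raise ValueError("continuous block has missing values; impute first")
        X = continuous.to_numpy(float)
        n = X.shape[0]
        sd = X.std(axis=0, ddof=0 if population_variance else 1)
        if np.any(sd == 0):
            bad = list(continuous.columns[sd == 0])
            raise ValueError(f"constant continuous column(s): {bad}")
        Z1 = (X - X.mean(axis=0)) / sd
        blocks.append(Z1)
        col_weights += [1.0] * Z1.shape[1]
        col_names += list(continuous.columns)
        var_of_col += list(continuous.columns)
        index = continuous.index
    if categorical is not None and categorical.shape[1]:
        if categorical.isna().any().any():
            raise ValueError("categorical block has missing values")
        n = len(categorical)
        for col in categorical.columns:
            levels = pd.unique(categorical[col])
            if len(levels) < 2:
                raise ValueError(f"single-level factor: {col}")
            G = pd.get_dummies(categorical[col]).to_numpy(float)
            freq = G.mean(axis=0)
            blocks.append(G - freq)
            col_weights += list(1.0 / freq)
            col_names += [f"{col}={lv}" for lv in pd.get_dummies(categorical[col]).columns]
            var_of_col += [col] * G.shape[1]
        index = categorical.index
    if not blocks:
        raise ValueError("no data")
    if continuous is not None and categorical is not None and len(continuous) and len(categorical):
        if len(continuous) != len(categorical):
            raise ValueError("blocks differ in row count")

    Z = np.hstack(blocks)
    n = Z.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows")
    cw = np.asarray(col_weights)
    # generalized SVD: row metric 1/n, column metric diag(cw)
    Zt = Z * np.sqrt(cw) / np.sqrt(n)
    U, svals, Vt = np.linalg.svd(Zt, full_matrices=False)
    eig = svals**2
    keep_pos = eig > 1e-12
    eig_all = eig[keep_pos]
    n_axes = min(n_axes, len(eig_all))

    # specimen scores: sqrt(n) U d ; loadings on original metric
    scores = (np.sqrt(n) * U[:, :n_axes]) * svals[:n_axes]
    A = (Vt[:n_axes].T / np.sqrt(cw)[:, None]) * svals[:n_axes]  # coordinates
    A_weighted = Vt[:n_axes].T * svals[:n_axes] * np.sqrt(cw)[:, None]

    # orient: largest |weighted loading| per axis is positive
    for a in range(n_axes):
        idx = np.argmax(np.abs(A_weighted[:, a]))
        if A_weighted[idx, a] < 0:
            scores[:, a] *= -1
            A[:, a] *= -1
            A_weighted[:, a] *= -1

    axes = [f"dim{a + 1}" for a in range(n_axes)]
    loadings = pd.DataFrame(A, index=col_names, columns=axes)
    # squared loadings per original variable: correlation^2 for continuous,
    # correlation ratio for categorical (sum of weighted squared coords / eig)
    sq = {}
    wl2 = A_weighted**2
    for var in dict.fromkeys(var_of_col):
        rows = [i for i, v in enumerate(var_of_col) if v == var]
        sq[var] = wl2[rows].sum(axis=0) / (n * np.ones(n_axes))
    squared = pd.DataFrame(sq).T
    squared.columns = axes

    n_cont = 0 if continuous is None else continuous.shape[1]
    n_cat_levels = sum(
        len(pd.unique(categorical[c])) for c in categorical.columns
    ) if categorical is not None and categorical.shape[1] else 0
    n_cat_vars = 0 if categorical is None else categorical.shape[1]
    total = n_cont + (n_cat_levels - n_cat_vars)
    return MixedPCAResult(
        eigenvalues=eig_all,
        scores=pd.DataFrame(scores, index=index, columns=axes),
        loadings=loadings,
        squared_loadings=squared,
        proportion=eig_all[:n_axes] / eig_all.sum(),
        total_inertia=float(total),
    )


def iterative_impute_pca(
    X: pd.DataFrame | np.ndarray,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> pd.DataFrame | np.ndarray:
    """Complete missing continuous cells by iterative low-rank PCA.

    Missing cells start at their column means; each iteration centers
    the data, reconstructs it from the top ``n_components`` singular
    directions, and rewrites only the missing cells, until the largest
    absolute change falls below ``tol``.  Non-convergence returns the
    last iterate with a warning.
    """
    import warnings

    is_frame = isinstance(X, pd.DataFrame)
    A = (X.to_numpy(float) if is_frame else np.asarray(X, float)).copy()
    n, p = A.shape
    if not 0 < n_components < min(n, p):
        raise ValueError("n_components must be in (0, min(rows, cols))")
    miss = np.isnan(A)
    if not miss.any():
        return X.copy() if is_frame else A
    if miss.all(axis=0).any():
        raise ValueError("a column is entirely missing")
    col_means = np.nanmean(A, axis=0)
    A[miss] = np.take(col_means, np.nonzero(miss)[1])
    prev_change = np.inf
    for _ in range(max_iter):
        mu = A.mean(axis=0)
        C = A - mu
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        recon = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components] + mu
        change = float(np.max(np.abs(A[miss] - recon[miss])))
        A[miss] = recon[miss]
        if change < tol:
            break
        prev_change = change
    else:
        warnings.warn(
            f"imputation did not converge (last change {prev_change:.3g})",
            stacklevel=2,
        )
    if is_frame:
        return pd.DataFrame(A, index=X.index, columns=X.columns)
    return A
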