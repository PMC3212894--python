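"""Principal-component reduction of image feature sets.

Each image set (CIR, RGB, CHM-derived) is reduced to its leading components;
a cross-correlation diagnostic quantifies overlap between the retained
scores of two sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ComponentSet", "pca_reduce", "cross_correlation"]


@dataclass
class ComponentSet:
    name: str
    loadings: np.ndarray  # (n_variables, k), orthonormal columns
    variance_fractions: np.ndarray  # (k,), non-increasing
    scores: np.ndarray  # (n_cells, k)
    variable_names: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def score_frame(self) -> pd.DataFrame:
        cols = [f"{self.name}{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.scores, columns=cols)


def pca_reduce(
    features: pd.DataFrame | np.ndarray,
    k: int = 8,
    name: str = "PC",
    scale: bool = True,
    kaiser: bool = False,
) -> ComponentSet:
    """PCA of the correlation matrix (``scale=True``) or covariance matrix.

    Constant columns are dropped with a warning before decomposition.  With
    ``kaiser=True`` the retained count is additionally capped at the number
    of eigenvalues exceeding the average eigenvalue.  Loading vectors are
    oriented so their largest-magnitude element is positive.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"v{i}" for i in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("features contain missing values; exclude nodata cells first")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, kpt in zip(names, keep) if not kpt]
        warnings.warn(f"dropping constant columns before PCA: {dropped}")
        X = X[:, keep]
        names = [n for n, kpt in zip(names, keep) if kpt]
        sd = sd[keep]
    if X.shape[1] < 1:
        raise ValueError("no non-constant variables to decompose")
    if k < 1:
        raise ValueError("k must be >= 1")

    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / sd
    # SVD of the centered (scaled) data = eigendecomposition of corr/cov
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / (X.shape[0] - 1)
    total = eigvals.sum()
    k_eff = min(k, len(eigvals))
    if kaiser:
        k_eff = min(k_eff, max(1, int((eigvals > eigvals.mean()).sum())))
    load = Vt[:k_eff].T.copy()
    # sign convention: largest-magnitude loading positive
    for j in range(k_eff):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    scores = Xc @ load
    fractions = eigvals[:k_eff] / total if total > 0 else np.zeros(k_eff)
    return ComponentSet(
        name=name,
        loadings=load,
        variance_fractions=fractions,
        scores=scores,
        variable_names=names,
    )


def cross_correlation(
    scores_a: np.ndarray | pd.DataFrame,
    scores_b: np.ndarray | pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson r between two score sets, with significance flags.

    Returns ``(r, significant)`` of shape ``(k_a, k_b)``; ``significant``
    marks ``p < alpha``.
    """
    A = np.asarray(scores_a, dtype=float)
    B = np.asarray(scores_b, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.shape[0] != B.shape[0]:
        raise ValueError("score sets must have equal row counts")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 rows for correlation analysis")
    ka, kb = A.shape[1], B.shape[1]
    r = np.empty((ka, kb))
    p = np.empty((ka, kb))
    for i in range(ka):
        for j in range(kb):
            r[i, j], p[i, j] = stats.pearsonr(A[:, i], B[:, j])
    return r, p < alpha
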