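"""Feature reduction and 2-D embedding: correlation filter, PCA, Sammon map.

The participant matrix is first pruned of highly collinear columns
(|Pearson rho| above a cutoff, default 0.85), then projected onto the
principal components of the correlation matrix, keeping components whose
eigenvalue exceeds 1 (the Kaiser rule — under unit-variance features a
component must explain more than one original variable's worth of variance
to be kept).  For visual similarity analysis the retained components are
mapped to the plane by Sammon's nonlinear mapping, which minimizes

    E = (1 / sum delta_ij) * sum_{i<j} (delta_ij - d_ij)^2 / delta_ij,

a stress that weights the preservation of *small* pairwise distances, so
near-neighbour structure survives the projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


def pearson_filter(matrix: pd.DataFrame, threshold: float = 0.85,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop columns too correlated with an earlier kept column.

    Columns are scanned in schema order; a column is dropped as soon as its
    |Pearson rho| with any already-kept column exceeds ``threshold``, so
    the earlier member of every offending pair survives.  Constant columns
    (undefined correlation) are dropped first with a warning.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    dropped: list[str] = []
    constant = [c for c in matrix.columns if matrix[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping {len(constant)} constant column(s): {constant}")
        dropped.extend(constant)
    cols = [c for c in matrix.columns if c not in constant]
    corr = matrix[cols].corr().abs()
    kept: list[str] = []
    for col in cols:
        if any(corr.at[col, k] > threshold for k in kept):
            dropped.append(col)
        else:
            kept.append(col)
    if len(kept) < 2:
        raise ValueError(
            f"fewer than 2 columns survive the |rho| > {threshold} filter")
    return matrix[kept], dropped


@dataclass
class PCAResult:
    """Kaiser-rule PCA of a standardized participant matrix.

    ``scores`` holds the retained component scores (rows follow the input);
    ``transform`` projects new rows into the same component space using the
    training mean/SD and loadings.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    n_retained: int
    loadings: np.ndarray          # columns = retained components
    mean: np.ndarray
    std: np.ndarray
    feature_names: list[str]

    def transform(self, new: pd.DataFrame) -> pd.DataFrame:
        Z = (new[self.feature_names].to_numpy(dtype=float) - self.mean) / self.std
        out = pd.DataFrame(Z @ self.loadings, index=new.index,
                           columns=self.scores.columns)
        return out


def pca_kaiser(matrix: pd.DataFrame, kaiser_cutoff: float = 1.0) -> PCAResult:
    """PCA on the correlation matrix, retaining eigenvalues > ``kaiser_cutoff``.

    Columns are z-scored (sample SD); component signs follow the
    convention that each component's largest-magnitude loading is positive.
    If no eigenvalue clears the cutoff (perfectly uncorrelated columns) the
    leading component alone is retained.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows")
    X = matrix.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    if np.any(std == 0):
        bad = [c for c, s in zip(matrix.columns, std) if s == 0]
        raise ValueError(f"zero-variance column(s) {bad}; filter them first")
    Z = (X - mean) / std
    corr = (Z.T @ Z) / (len(Z) - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    n_retained = int(np.sum(evals > kaiser_cutoff)) or 1
    load = evecs[:, :n_retained].copy()
    for j in range(n_retained):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]
    scores = pd.DataFrame(Z @ load, index=matrix.index,
                          columns=[f"PC{j + 1}" for j in range(n_retained)])
    return PCAResult(scores, evals, n_retained, load, mean, std,
                     list(matrix.columns))


def _sammon_stress_grad(Y: np.ndarray, delta: np.ndarray, c: float,
                        active: np.ndarray) -> tuple[float, np.ndarray]:
    d = squareform(pdist(Y))
    d[d == 0] = 1e-12
    np.fill_diagonal(d, 1.0)
    diff = delta - d
    w = np.where(active, 1.0 / delta, 0.0)
    stress = float((w * diff ** 2)[np.triu_indices_from(d, 1)].sum() / c)
    coef = np.where(active, diff / (np.where(active, delta, 1.0) * d), 0.0)
    grad = np.zeros_like(Y)
    for a in range(Y.shape[1]):
        dy = Y[:, a][:, None] - Y[:, a][None, :]
        grad[:, a] = (-2.0 / c) * (coef * dy).sum(axis=1)
    return stress, grad


def sammon_map(X: np.ndarray | pd.DataFrame, n_dims: int = 2,
               iters: int = 500, tol: float = 1e-9,
               seed: int = 0) -> tuple[np.ndarray | pd.DataFrame, float]:
    """Project rows of X to ``n_dims`` by minimizing the Sammon stress.

    Gradient descent with step-halving (the stress never increases),
    initialized from the first ``n_dims`` principal-component scores of X
    (random if degenerate).  Duplicate rows — zero input distance — are
    excluded from the stress with a warning.  Returns the coordinates and
    the final stress.
    """
    ids = X.index if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows")
    delta = squareform(pdist(X))
    active = np.ones_like(delta, dtype=bool)
    np.fill_diagonal(active, False)
    zero = (delta == 0) & active
    if zero.any():
        warnings.warn("duplicate rows: zero-distance pairs excluded from stress")
        active &= ~zero
    if not active.any():
        raise ValueError("all pairwise input distances are zero")
    delta_safe = np.where(active, delta, 1.0)
    c = delta[np.triu_indices_from(delta, 1)].sum()

    # PCA initialization (fall back to random for degenerate input)
    Xc = X - X.mean(axis=0)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s.size >= n_dims and s[n_dims - 1] > 1e-12:
        Y = Xc @ Vt[:n_dims].T
    else:
        Y = np.random.default_rng(seed).normal(scale=1e-2, size=(n, n_dims))

    stress, grad = _sammon_stress_grad(Y, delta_safe, c, active)
    alpha = 0.3
    for _ in range(iters):
        step_ok = False
        a = alpha
        for _ in range(40):
            Y_new = Y - a * grad
            new_stress, new_grad = _sammon_stress_grad(Y_new, delta_safe, c, active)
            if new_stress <= stress:
                step_ok = True
                break
            a /= 2.0
        if not step_ok:
            break
        rel = (stress - new_stress) / stress if stress > 0 else 0.0
        Y, stress, grad = Y_new, new_stress, new_grad
        alpha = min(a * 2.0, 1.0)
        if rel < tol:
            break
    if ids is not None:
        cols = ["x", "y"] if n_dims == 2 else [f"dim{i + 1}" for i in range(n_dims)]
        return pd.DataFrame(Y, index=ids, columns=cols), stress
    return Y, stress
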