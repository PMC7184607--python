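"""Exploratory factor analysis of signature-gene expression.

Highly correlated genes are grouped into latent factors: the Pearson
correlation matrix of the genes is factored by iterated principal-axis
extraction (communalities initialized at squared multiple correlations
and refined to convergence), the loading matrix is rotated obliquely
with oblimin (quartimin criterion, gradient-projection algorithm), and
subject scores are computed by the regression (Thomson) method.  A gene
is assigned to the factor holding its largest absolute pattern loading
when that loading reaches the cutoff (0.3 by default); otherwise it is
left unassigned, mirroring the "no factor assignment" group such
analyses report.

The number of factors k is a required parameter; ``parallel_analysis``
suggests one but never chooses silently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import FactorSolution, NormalizedExpr
from .assoc import gene_assoc

__all__ = [
    "GeneFactorAnalysis",
    "fit_factors",
    "assign_loadings",
    "factor_assoc",
    "parallel_analysis",
]


def _principal_axis(R: np.ndarray, k: int, max_iter: int = 200,
                    tol: float = 1e-7) -> np.ndarray:
    """Iterated principal-axis loadings (n_vars x k) from a correlation
    matrix, communalities started at squared multiple correlations."""
    n = R.shape[0]
    # SMC initial communalities; regularize in case R is near-singular
    Rinv = np.linalg.inv(R + 1e-8 * np.eye(n))
    h2 = np.clip(1.0 - 1.0 / np.diag(Rinv), 0.0, 1.0 - 1e-6)
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        evals, evecs = np.linalg.eigh(Rr)
        idx = np.argsort(evals)[::-1][:k]
        lam = np.clip(evals[idx], 0.0, None)
        L = evecs[:, idx] * np.sqrt(lam)
        h2_new = np.clip((L ** 2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    Rr = R.copy()
    np.fill_diagonal(Rr, h2)
    evals, evecs = np.linalg.eigh(Rr)
    idx = np.argsort(evals)[::-1][:k]
    L = evecs[:, idx] * np.sqrt(np.clip(evals[idx], 0.0, None))
    return L


def _quartimin(L: np.ndarray):
    """Quartimin criterion value and gradient (oblimin with gamma=0)."""
    L2 = L ** 2
    k = L.shape[1]
    N = np.ones((k, k)) - np.eye(k)
    f = float(np.sum(L2 * (L2 @ N)) / 4.0)
    G = L * (L2 @ N)
    return f, G


def _oblimin_rotate(A: np.ndarray, max_iter: int = 500, tol: float = 1e-6):
    """Oblique gradient-projection rotation (Bernaards-Jennrich).

    Returns the rotated pattern matrix and the factor correlation
    matrix Phi.  Deterministic: starts from the identity."""
    k = A.shape[1]
    if k == 1:
        return A.copy(), np.ones((1, 1))
    T = np.eye(k)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0, keepdims=True)
        s = np.sqrt((Gp ** 2).sum())
        if s < tol:
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            X /= np.sqrt((X ** 2).sum(axis=0, keepdims=True))
            Ti = np.linalg.inv(X)
            Lt = A @ Ti.T
            ft, Gq = _quartimin(Lt)
            if ft < f - 0.5 * s ** 2 * al:
                break
            al /= 2.0
        T, f, L = X, ft, Lt
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi


def _canonicalize(L: np.ndarray, Phi: np.ndarray):
    """Deterministic presentation: factors ordered by explained sum of
    squared loadings (descending) and signed so each column's loading
    sum is non-negative."""
    ss = (L ** 2).sum(axis=0)
    order = np.argsort(-ss, kind="stable")
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    signs = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    return L, Phi


class GeneFactorAnalysis(BaseEstimator, TransformerMixin):
    """Oblique exploratory factor analysis estimator.

    Parameters
    ----------
    k : int
        Number of factors to extract (required; the published analysis
        of this signature used seven).
    cutoff : float
        Absolute-loading cutoff for assigning a gene to a factor.
    """

    def __init__(self, k: int = 7, cutoff: float = 0.3):
        self.k = k
        self.cutoff = cutoff

    def fit(self, N, y=None):
        values = N.values if isinstance(N, NormalizedExpr) else N
        genes = list(values.index)
        X = values.to_numpy(dtype=float).T  # subjects x genes
        n, g = X.shape
        if self.k >= g:
            raise ValueError("k must be smaller than the number of genes")
        if n <= self.k:
            raise ValueError("need more subjects than factors")
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant gene expression; drop before FA")
        Z = (X - X.mean(axis=0)) / sd
        R = np.corrcoef(Z, rowvar=False)

        A = _principal_axis(R, self.k)
        L, Phi = _oblimin_rotate(A)
        L, Phi = _canonicalize(L, Phi)

        cols = [f"F{j + 1}" for j in range(self.k)]
        self.loadings_ = pd.DataFrame(L, index=genes, columns=cols)
        self.phi_ = Phi
        self.communalities_ = pd.Series(
            ((L @ Phi) * L).sum(axis=1), index=genes
        )
        # regression (Thomson) scores: W = R^-1 * structure matrix
        S = L @ Phi
        W = np.linalg.solve(R + 1e-10 * np.eye(g), S)
        self.weights_ = W
        self._genes = genes
        self.scores_ = pd.DataFrame(Z @ W, index=values.columns, columns=cols)
        self.assignment_ = assign_loadings(self.loadings_, self.cutoff)
        return self

    def transform(self, N) -> pd.DataFrame:
        values = N.values if isinstance(N, NormalizedExpr) else N
        X = values.loc[self._genes].to_numpy(dtype=float).T
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        return pd.DataFrame(
            Z @ self.weights_, index=values.columns,
            columns=self.loadings_.columns,
        )

    def solution_(self) -> FactorSolution:
        return FactorSolution(
            loadings=self.loadings_, phi=self.phi_, scores=self.scores_,
            assignment=self.assignment_,
        )


def fit_factors(N, k: int, cutoff: float = 0.3) -> FactorSolution:
    """Fit the k-factor oblimin solution; see :class:`GeneFactorAnalysis`."""
    return GeneFactorAnalysis(k=k, cutoff=cutoff).fit(N).solution_()


def assign_loadings(loadings: pd.DataFrame, cutoff: float = 0.3) -> pd.Series:
    """Gene -> factor label of the maximal |loading| when it reaches
    the cutoff, else <NA> ("no factor assignment")."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    absload = loadings.abs()
    best = absload.idxmax(axis=1)
    top = absload.max(axis=1)
    return pd.Series(
        np.where(top >= cutoff, best, pd.NA), index=loadings.index,
        dtype="object", name="factor",
    )


def factor_assoc(solution: FactorSolution, predictor,
                 mask=None) -> pd.DataFrame:
    """OLS of each factor score on the quartile-median predictor."""
    scores = solution.scores if isinstance(solution, FactorSolution) else solution
    return gene_assoc(scores.T, predictor, mask=mask, stratum="factors")


def parallel_analysis(values: pd.DataFrame, n_draws: int = 50,
                      quantile: float = 0.95, seed: int = 0) -> int:
    """Suggest k: number of correlation eigenvalues exceeding the given
    quantile of eigenvalues from same-shaped independent normal data."""
    X = values.to_numpy(dtype=float).T
    n, g = X.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_draws, g))
    for i in range(n_draws):
        Z = rng.normal(size=(n, g))
        null[i] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    ref = np.quantile(null, quantile, axis=0)
    return int(np.sum(obs > ref))
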