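"""Exposure-expression association and paired tissue comparison.

The exposure predictor follows the epidemiologic quartile-median
construction: urinary MEP is natural-log transformed, subjects are
quartiled on the interpolated quartile cut points (boundary values go
to the lower quartile), and each subject receives the median ln-MEP of
its quartile.  Per-gene association is a Gaussian GLM with identity
link — ordinary least squares of log2 expression on that scalar
predictor — run before and after stratifying by menopausal status, and
optionally within AR-positive subjects (AR expression at or above the
Tukey lower whisker, Q1 - 1.5*IQR).  Adjacent-vs-tumor comparison uses
the Wilcoxon signed-rank test per gene with BH adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import NormalizedExpr
from .de import bh_adjust

__all__ = [
    "QuartileMedianBinner",
    "quartile_median_predictor",
    "gene_assoc",
    "ar_positive_mask",
    "paired_wilcoxon",
]


class QuartileMedianBinner(BaseEstimator, TransformerMixin):
    """Transformer form of the quartile-median predictor.

    ``fit`` learns the ln-scale quartile cut points and quartile
    medians; ``transform`` maps concentrations onto the medians learned
    at fit time, so the predictor is reusable on held-out subjects.
    """

    def __init__(self, log_transform: bool = True):
        self.log_transform = log_transform

    def fit(self, X, y=None):
        x = self._to_log(X)
        if x.size < 4:
            raise ValueError("need >=4 subjects to quartile")
        self.cuts_ = np.quantile(x, [0.25, 0.5, 0.75])
        bins = self._bin(x)
        self.medians_ = np.array(
            [np.median(x[bins == q]) if np.any(bins == q) else np.nan
             for q in range(4)]
        )
        return self

    def transform(self, X) -> np.ndarray:
        x = self._to_log(X)
        return self.medians_[self._bin(x)]

    def _to_log(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        if self.log_transform:
            if np.any(x <= 0):
                raise ValueError("concentrations must be positive")
            x = np.log(x)
        return x

    def _bin(self, x: np.ndarray) -> np.ndarray:
        # boundary values fall in the lower quartile (left-closed at min)
        return np.searchsorted(self.cuts_, x, side="left").clip(0, 3)


def quartile_median_predictor(mep, log_transform: bool = True) -> np.ndarray:
    """Per-subject quartile-median ln-MEP predictor."""
    binner = QuartileMedianBinner(log_transform=log_transform).fit(mep)
    return binner.transform(mep)


def _ols_slope(x: np.ndarray, Y: np.ndarray):
    """Vectorized simple OLS of each row of Y on x.

    Returns (beta, p, perfect_fit) arrays.  A constant response gives
    beta 0 and p 1; an exact fit with nonzero slope reports p 0 with
    the perfect-fit flag set.
    """
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = Y - Y.mean(axis=1, keepdims=True)
    beta = (yc @ xc) / sxx
    rss = (yc ** 2).sum(axis=1) - beta ** 2 * sxx
    rss = np.maximum(rss, 0.0)
    sigma_sq = rss / (n - 2)
    se = np.sqrt(sigma_sq / sxx)

    const_y = (yc ** 2).sum(axis=1) == 0
    perfect = (~const_y) & (sigma_sq <= 1e-28 * (yc ** 2).sum(axis=1) / (n - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    beta = np.where(const_y, 0.0, beta)
    p = np.where(const_y, 1.0, np.where(perfect, 0.0, p))
    return beta, p, perfect


def gene_assoc(N, predictor, mask=None, stratum: str = "all") -> pd.DataFrame:
    """Per-gene OLS of log2 expression on the scalar predictor.

    ``N`` is a :class:`NormalizedExpr` or a genes x samples DataFrame;
    ``mask`` restricts to a stratum (boolean per sample).  Returns a
    gene-indexed table [beta, p, n, stratum, perfect_fit].
    """
    values = N.values if isinstance(N, NormalizedExpr) else N
    x = np.asarray(predictor, dtype=float).ravel()
    if x.size != values.shape[1]:
        raise ValueError("predictor length must match sample count")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).ravel()
        values = values.loc[:, mask]
        x = x[mask]
    n = x.size
    if n < 4:
        raise ValueError("need >=4 subjects in the stratum")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor in the stratum")
    beta, p, perfect = _ols_slope(x, values.to_numpy())
    return pd.DataFrame(
        {
            "beta": beta,
            "p": p,
            "n": n,
            "stratum": stratum,
            "perfect_fit": perfect,
        },
        index=values.index,
    )


def ar_positive_mask(ar_expr) -> np.ndarray:
    """True for subjects at or above the Tukey lower whisker
    (Q1 - 1.5*IQR) of AR expression, i.e. not low outliers."""
    x = np.asarray(ar_expr, dtype=float).ravel()
    if x.size < 5:
        raise ValueError("need >=5 subjects for the whisker fence")
    q1, q3 = np.percentile(x, [25, 75])
    fence = q1 - 1.5 * (q3 - q1)
    return x >= fence


def _signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p: exact for n <= 25 without ties in the
    absolute differences, else normal approximation with continuity
    correction.  Zero differences are dropped by the caller."""
    n = diffs.size
    ranks = np.abs(diffs)
    exact_ok = n <= 25 and np.unique(ranks).size == n
    method = "exact" if exact_ok else "approx"
    res = stats.wilcoxon(diffs, alternative="two-sided", method=method,
                         correction=True, zero_method="wilcox")
    return float(res.pvalue)


def paired_wilcoxon(N_adj: pd.DataFrame, N_tum: pd.DataFrame,
                    pairs=None, fdr: float = 0.05) -> pd.DataFrame:
    """Per-gene adjacent-minus-tumor signed-rank test with BH FDR.

    ``N_adj`` and ``N_tum`` are genes x samples log2 tables whose
    columns are matched pairs (optionally reordered through ``pairs``,
    a list of (adjacent, tumor) column pairs).  Genes with fewer than
    three nonzero paired differences get no p-value, with a reason.
    """
    if pairs is not None:
        adj_cols = [a for a, _ in pairs]
        tum_cols = [t for _, t in pairs]
        N_adj = N_adj[adj_cols]
        N_tum = N_tum[tum_cols]
    if N_adj.shape[1] != N_tum.shape[1]:
        raise ValueError("unequal numbers of adjacent and tumor columns")
    if N_adj.shape[1] < 3:
        raise ValueError("need >=3 complete pairs")
    if not N_adj.index.equals(N_tum.index):
        raise ValueError("gene indices differ between tissues")

    diffs = N_adj.to_numpy() - N_tum.to_numpy()
    rows = []
    for i, gene in enumerate(N_adj.index):
        d = diffs[i]
        nz = d[d != 0]
        med = float(np.median(d))
        if nz.size < 3:
            rows.append((gene, np.nan, 0, med, "fewer than 3 nonzero pairs"))
            continue
        rows.append((gene, _signed_rank_p(nz), int(np.sign(med)), med, ""))
    out = pd.DataFrame(
        rows, columns=["gene", "p", "direction", "median_diff", "note"]
    ).set_index("gene")
    tested = out["p"].notna()
    q = pd.Series(np.nan, index=out.index)
    if tested.any():
        q[tested] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    out["significant"] = out["q"] < fdr
    return out
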