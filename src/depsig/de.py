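"""Moderated two-group differential expression (empirical-Bayes t).

Per gene, the treated-minus-control log2 fold change is tested with a
pooled-variance t-statistic whose per-gene variance is shrunk toward a
prior estimated from the whole ensemble of residual variances:

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g    = log2fc_g / (s~_g * sqrt(1/n_t + 1/n_c))

with d_g = n_t + n_c - 2 residual degrees of freedom and the moderated t
referred to a t distribution on d0 + d_g degrees of freedom.  The prior
(d0, s0^2) is estimated by the method of moments on the log residual
variances (Smyth's F-distribution fit): with
e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2),

    trigamma(d0/2) = var(e) - mean(trigamma(d_g/2))
    s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2))

and d0 = +inf (full shrinkage to s0^2) when the moment equation has no
positive solution.  Genes with zero residual variance are excluded from
the moment fit but still receive the moderated variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests
from sklearn.base import BaseEstimator

from .containers import ExprMatrix

__all__ = [
    "EBayesParams",
    "ModeratedTTest",
    "fit_de",
    "bh_adjust",
    "call_degs",
    "estimate_ebayes",
]


@dataclass
class EBayesParams:
    """Empirical-Bayes prior: degrees of freedom d0 and variance s0^2."""

    d0: float
    s0_sq: float


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_ebayes(s_sq: np.ndarray, df: float) -> EBayesParams:
    """Method-of-moments fit of the variance prior from per-gene
    residual variances ``s_sq`` with common residual df ``df``."""
    s_sq = np.asarray(s_sq, dtype=float)
    pos = s_sq > 0
    if not pos.any():
        raise ValueError("all residual variances are zero; prior undefined")
    z = np.log(s_sq[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if len(e) < 2:
        return EBayesParams(np.inf, float(np.exp(emean)))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return EBayesParams(np.inf, float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(
        np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return EBayesParams(d0, s0_sq)


class ModeratedTTest(BaseEstimator):
    """Two-arm moderated t-test estimator.

    Parameters
    ----------
    d0 : float or None
        Prior degrees of freedom.  ``None`` (default) estimates the
        prior from the data; ``0`` recovers the ordinary pooled t;
        ``inf`` shrinks every gene fully to the prior variance.
    s0_sq : float or None
        Prior variance; only used with a forced ``d0``.  ``None``
        estimates it by the method of moments.
    """

    def __init__(self, d0: float | None = None, s0_sq: float | None = None):
        self.d0 = d0
        self.s0_sq = s0_sq

    def fit(self, M: ExprMatrix, treated, control):
        treated, control = list(treated), list(control)
        if len(treated) < 2 or len(control) < 2:
            raise ValueError("each arm needs >=2 samples")
        if set(treated) & set(control):
            raise ValueError("arms must be disjoint")

        t_vals = M.values[treated].to_numpy()
        c_vals = M.values[control].to_numpy()
        n_t, n_c = t_vals.shape[1], c_vals.shape[1]
        df = n_t + n_c - 2

        log2fc = t_vals.mean(axis=1) - c_vals.mean(axis=1)
        ss = (
            ((t_vals - t_vals.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            + ((c_vals - c_vals.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        )
        s_sq = ss / df

        if self.d0 is None and self.s0_sq is None:
            prior = estimate_ebayes(s_sq, df)
        else:
            d0 = 0.0 if self.d0 is None else float(self.d0)
            if self.s0_sq is not None:
                s0_sq = float(self.s0_sq)
            elif d0 > 0:
                s0_sq = estimate_ebayes(s_sq, df).s0_sq
            else:
                s0_sq = 1.0  # irrelevant at d0 = 0
            prior = EBayesParams(d0, s0_sq)

        if np.isinf(prior.d0):
            s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
            df_total = np.inf
        elif prior.d0 == 0:
            s_tilde_sq = s_sq
            df_total = float(df)
        else:
            s_tilde_sq = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
            df_total = prior.d0 + df

        se = np.sqrt(s_tilde_sq * (1.0 / n_t + 1.0 / n_c))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = np.where(se > 0, log2fc / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

        self.prior_ = prior
        self.results_ = pd.DataFrame(
            {
                "log2fc": log2fc,
                "t": t_mod,
                "df": df_total,
                "p": p,
                "q": bh_adjust(p),
            },
            index=M.genes,
        )
        return self


def fit_de(M: ExprMatrix, treated, control, d0: float | None = None,
           s0_sq: float | None = None) -> pd.DataFrame:
    """Moderated DE table (gene x [log2fc, t, df, p, q])."""
    est = ModeratedTTest(d0=d0, s0_sq=s0_sq).fit(M, treated, control)
    return est.results_


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(table: pd.DataFrame, fdr: float = 0.25,
              fc_min: float = 1.5) -> pd.DataFrame:
    """Significance calls: q < fdr and |log2fc| >= log2(fc_min).

    Returns the called subset with a ``direction`` column (+1 up, -1
    down, treated relative to control).
    """
    if fc_min <= 1:
        raise ValueError("fc_min must exceed 1")
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    lfc_min = np.log2(fc_min)
    called = table[(table["q"] < fdr) & (table["log2fc"].abs() >= lfc_min)]
    called = called.copy()
    called["direction"] = np.sign(called["log2fc"]).astype(int)
    return called
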