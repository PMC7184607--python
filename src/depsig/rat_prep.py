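"""Gene filtering of the normalized rodent expression matrix.

Two filters are applied before differential expression: an intensity
filter that keeps genes whose expression is high in at least one
experimental group, and a variability filter that keeps the top fraction
of genes by across-sample interquartile range.

The intensity threshold is the given percentile of the pooled
distribution of all per-gene per-group means (one global threshold); a
gene passes when its maximum group mean strictly exceeds it.  Quantiles
use linear interpolation between order statistics throughout the
package, and filter membership depends on that convention.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ExprMatrix


def _group_means(M: ExprMatrix) -> pd.DataFrame:
    """Per-gene mean within each experimental group (genes x groups)."""
    out = {}
    for group in pd.unique(M.groups):
        cols = M.group_samples(group)
        if not cols:
            raise ValueError(f"experimental group {group!r} is empty")
        out[group] = M.values[cols].mean(axis=1)
    return pd.DataFrame(out)


def intensity_filter(M: ExprMatrix, percentile: float = 30.0) -> list[str]:
    """Keep genes whose maximum group mean strictly exceeds the pooled
    ``percentile`` of all per-gene per-group means."""
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    means = _group_means(M)
    threshold = float(np.percentile(means.to_numpy().ravel(), percentile))
    keep = means.max(axis=1) > threshold
    return list(means.index[keep])


def iqr_filter(M: ExprMatrix, keep_frac: float = 0.5) -> list[str]:
    """Keep the ``ceil(keep_frac * n_genes)`` genes with largest
    across-sample IQR; ties at the cut break by gene ID (ascending)."""
    if not 0 < keep_frac <= 1:
        raise ValueError("keep_frac must be in (0, 1]")
    if M.values.shape[1] < 4:
        raise ValueError("IQR filter needs >=4 samples")
    vals = M.values.to_numpy()
    iqr = np.percentile(vals, 75, axis=1) - np.percentile(vals, 25, axis=1)
    order = sorted(zip(-iqr, M.genes))  # IQR desc, then gene ID asc
    n_keep = math.ceil(keep_frac * len(order))
    return [gene for _, gene in order[:n_keep]]


class IntensityFilter(BaseEstimator):
    """Selector form of :func:`intensity_filter` (fit/get_support)."""

    def __init__(self, percentile: float = 30.0):
        self.percentile = percentile

    def fit(self, M: ExprMatrix, y=None):
        self.selected_ = intensity_filter(M, self.percentile)
        return self

    def get_support(self) -> list[str]:
        return list(self.selected_)

    def transform(self, M: ExprMatrix) -> ExprMatrix:
        return M.subset_genes(self.selected_)


class IQRFilter(BaseEstimator):
    """Selector form of :func:`iqr_filter` (fit/get_support)."""

    def __init__(self, keep_frac: float = 0.5):
        self.keep_frac = keep_frac

    def fit(self, M: ExprMatrix, y=None):
        self.selected_ = iqr_filter(M, self.keep_frac)
        return self

    def get_support(self) -> list[str]:
        return list(self.selected_)

    def transform(self, M: ExprMatrix) -> ExprMatrix:
        return M.subset_genes(self.selected_)
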