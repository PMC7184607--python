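"""Small descriptive-statistics helpers for cohort characteristic tables."""

from __future__ import annotations

import pandas as pd


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` out of ``total``, rounded for tabulation
    (e.g. 262 of 294 -> 89.1)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must be in [0, total]")
    return round(100.0 * count / total, ndigits)


def categorical_summary(series: pd.Series, ndigits: int = 1) -> pd.DataFrame:
    """'n (percent)' rows per category, in order of first appearance."""
    counts = series.value_counts(sort=False)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "n": counts,
            "percent": [percent(int(c), total, ndigits) for c in counts],
        }
    )
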