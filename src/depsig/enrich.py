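"""Fisher's-exact over-representation against a gene-set library.

For each set in a TF-target-style library, the query genes are
cross-tabulated against the set within a fixed gene universe and tested
one-sided for enrichment (hypergeometric upper tail), with BH
adjustment across all tested sets.  The universe defaults to the
measured panel, conditioning on what was measurable rather than on the
genome.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetLibrary
from .de import bh_adjust

__all__ = ["fisher_exact_2x2", "enrich_library"]


def fisher_exact_2x2(a: int, b: int, c: int, d: int):
    """One-sided (enrichment) Fisher p and sample odds ratio.

    ``p = P(X >= a)`` for X hypergeometric with population N = a+b+c+d,
    K = a+b successes and n = a+c draws; OR = ad/bc (infinite when
    bc = 0 and ad > 0, undefined 0/0 reported as nan).
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("degenerate empty table")
    p = float(stats.hypergeom.sf(a - 1, n_total, a + b, a + c))
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return min(p, 1.0), odds


def enrich_library(query, lib: GeneSetLibrary, universe,
                   fdr: float = 0.05) -> pd.DataFrame:
    """Per-set enrichment table, BH-adjusted and sorted by p.

    Query genes must lie within the universe; library sets are
    intersected with the universe before testing.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        raise ValueError(
            f"query genes outside the universe: {sorted(outside)[:10]}"
        )

    rows = []
    for name, (desc, genes) in lib.items():
        members = set(genes) & universe
        if not members:
            continue
        overlap = sorted(query & members)
        a = len(overlap)
        b = len(members) - a
        c = len(query) - a
        d = len(universe) - a - b - c
        p, odds = fisher_exact_2x2(a, b, c, d)
        rows.append(
            {
                "set": name,
                "description": desc,
                "overlap": a,
                "set_size": len(members),
                "odds_ratio": odds,
                "p": p,
                "overlap_genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(
        rows, columns=["set", "description", "overlap", "set_size",
                       "odds_ratio", "p", "overlap_genes"],
    ).set_index("set")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr
        out = out.sort_values(["p", "set"], kind="stable")
    return out
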