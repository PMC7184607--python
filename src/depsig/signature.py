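"""Subsample-consensus signature derivation.

A small two-arm experiment (five animals per arm) is made robust by
enumerating every way of choosing k of n samples in each arm (k = 4 of
5 gives 5 x 5 = 25 rounds), running the moderated differential-
expression test on each round, and keeping genes called significant with
a consistent direction in at least a configurable fraction of rounds.
The consensus set is then ranked by the absolute difference in median
expression between the full arms, truncated to the top K, translated to
human symbols through an ortholog map, and merged across the parity
panels.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ExprMatrix, SignaturePanel
from .de import call_degs, fit_de

log = logging.getLogger(__name__)

__all__ = [
    "enumerate_rounds",
    "ConsensusSignature",
    "consensus_signature",
    "rank_top_k",
    "map_orthologs",
    "merge_panels",
    "derive_signature",
]


def enumerate_rounds(n_treated: int, n_control: int, k: int) -> list[tuple]:
    """All C(n_t,k) x C(n_c,k) (treated-subset, control-subset) index
    pairs in lexicographic order."""
    if k <= 0:
        raise ValueError("subsample size k must be positive")
    if k > min(n_treated, n_control):
        raise ValueError("k exceeds an arm size")
    return [
        (t, c)
        for t in combinations(range(n_treated), k)
        for c in combinations(range(n_control), k)
    ]


class ConsensusSignature(BaseEstimator):
    """Leave-out subsample consensus differential-expression estimator.

    Parameters mirror the published thresholds: a lenient FDR of 25%
    with a fold change of at least 1.5 within each round, subsamples of
    ``subsample_k`` = 4 out of each five-animal arm, and a
    direction-consistent support requirement of ``min_support`` of the
    rounds (how the rounds were combined in the original analysis is not
    specified; the support fraction is reported per gene so the choice
    can be audited).
    """

    def __init__(self, fdr: float = 0.25, fc_min: float = 1.5,
                 subsample_k: int = 4, min_support: float = 0.8):
        self.fdr = fdr
        self.fc_min = fc_min
        self.subsample_k = subsample_k
        self.min_support = min_support

    def fit(self, M: ExprMatrix, treated, control):
        treated, control = list(treated), list(control)
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must be in (0, 1]")
        rounds = enumerate_rounds(len(treated), len(control), self.subsample_k)

        up = pd.Series(0, index=M.genes, dtype=int)
        down = pd.Series(0, index=M.genes, dtype=int)
        for t_idx, c_idx in rounds:
            table = fit_de(
                M, [treated[i] for i in t_idx], [control[i] for i in c_idx]
            )
            called = call_degs(table, fdr=self.fdr, fc_min=self.fc_min)
            up[called.index[called["direction"] > 0]] += 1
            down[called.index[called["direction"] < 0]] += 1

        n_rounds = len(rounds)
        frac_up = up / n_rounds
        frac_down = down / n_rounds
        support = pd.concat([frac_up, frac_down], axis=1).max(axis=1)
        direction = np.where(frac_up >= frac_down, 1, -1)

        conflict = (frac_up >= self.min_support) & (frac_down >= self.min_support)
        for gene in M.genes[conflict]:
            msg = (f"gene {gene} called in opposite directions above the "
                   f"support threshold; excluded from the consensus")
            log.warning(msg)
            warnings.warn(msg, stacklevel=2)
        keep = (support >= self.min_support) & ~conflict

        self.n_rounds_ = n_rounds
        self.support_ = pd.DataFrame(
            {"support": support, "direction": direction}, index=M.genes
        )
        self.signature_ = self.support_[keep].copy()
        return self


def consensus_signature(M: ExprMatrix, treated, control, fdr: float = 0.25,
                        fc_min: float = 1.5, subsample_k: int = 4,
                        min_support: float = 0.8) -> pd.DataFrame:
    """Consensus gene table (gene x [support, direction]); see
    :class:`ConsensusSignature`."""
    est = ConsensusSignature(fdr, fc_min, subsample_k, min_support)
    return est.fit(M, treated, control).signature_


def rank_top_k(M: ExprMatrix, treated, control, genes,
               k_top: int = 100) -> pd.DataFrame:
    """Rank ``genes`` by |median(treated) - median(control)| descending
    (ties by gene ID) and keep the top ``k_top``."""
    if k_top <= 0:
        raise ValueError("k_top must be positive")
    genes = list(genes)
    missing = set(genes) - set(M.genes)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
    sub = M.values.loc[genes]
    diff = sub[list(treated)].median(axis=1) - sub[list(control)].median(axis=1)
    order = sorted(zip(-diff.abs(), diff.index))
    kept = [g for _, g in order[:k_top]]
    return pd.DataFrame(
        {"gene": kept, "median_diff": diff[kept].to_numpy()}
    ).set_index("gene")


def map_orthologs(genes, ortholog_map: pd.DataFrame):
    """Translate rat genes to human symbols through a two-column map.

    Returns ``(mapped, unmapped, sources)``: human symbols deduplicated
    preserving first occurrence, the rat genes without an entry, and a
    symbol -> list-of-rat-genes record of every contributing source.
    """
    lut = dict(zip(ortholog_map["rat_gene"], ortholog_map["human_gene"]))
    if len(lut) < len(ortholog_map):
        raise ValueError("ortholog map assigns a rat gene to two symbols")
    mapped: list[str] = []
    sources: dict[str, list[str]] = {}
    unmapped: list[str] = []
    for g in genes:
        sym = lut.get(g)
        if sym is None:
            unmapped.append(g)
            continue
        if sym not in sources:
            mapped.append(sym)
            sources[sym] = []
        sources[sym].append(g)
    return mapped, unmapped, sources


def merge_panels(parous: pd.DataFrame, nulliparous: pd.DataFrame) -> SignaturePanel:
    """Union of the parity panels with origin labels.

    Each input is a DataFrame indexed by human gene symbol with columns
    ``direction`` and optionally ``score`` and ``support``.  A gene in
    both panels must agree in direction and is labelled ``both``.
    """
    rows = []
    shared = set(parous.index) & set(nulliparous.index)
    for gene in shared:
        if int(parous.loc[gene, "direction"]) != int(nulliparous.loc[gene, "direction"]):
            raise ValueError(
                f"gene {gene} has conflicting directions in the two panels"
            )
    for origin, panel in (("parous", parous), ("nulliparous", nulliparous)):
        for gene, row in panel.iterrows():
            if origin == "nulliparous" and gene in shared:
                continue
            rows.append(
                {
                    "gene": gene,
                    "direction": int(row["direction"]),
                    "origin": "both" if gene in shared else origin,
                    "score": float(row.get("score", np.nan)),
                    "support": float(row.get("support", np.nan)),
                }
            )
    return SignaturePanel(pd.DataFrame(rows, columns=[
        "gene", "direction", "origin", "score", "support"
    ]))


def derive_signature(M: ExprMatrix, ortholog_map: pd.DataFrame,
                     fdr: float = 0.25, fc_min: float = 1.5,
                     subsample_k: int = 4, min_support: float = 0.8,
                     top_k: int = 100):
    """Full rodent-side derivation: per-parity consensus, top-K ranking
    of the parous panel, ortholog translation, and panel merge.

    Returns ``(SignaturePanel, details)`` where details holds the
    per-parity consensus tables and unmapped gene lists.
    """
    details: dict = {}
    panels = {}
    for parity in ("parous", "nulliparous"):
        treated = M.group_samples(f"{parity}_dep")
        control = M.group_samples(f"{parity}_vehicle")
        cons = consensus_signature(
            M, treated, control, fdr, fc_min, subsample_k, min_support
        )
        details[f"{parity}_consensus"] = cons
        genes = list(cons.index)
        if parity == "parous" and genes:
            ranked = rank_top_k(M, treated, control, genes, k_top=top_k)
            genes = list(ranked.index)
            score = ranked["median_diff"].abs()
        else:
            score = pd.Series(np.nan, index=genes)
        mapped, unmapped, sources = map_orthologs(genes, ortholog_map)
        details[f"{parity}_unmapped"] = unmapped
        rat_of = {h: r[0] for h, r in sources.items()}
        panels[parity] = pd.DataFrame(
            {
                "direction": [int(cons.loc[rat_of[h], "direction"]) for h in mapped],
                "support": [float(cons.loc[rat_of[h], "support"]) for h in mapped],
                "score": [float(score.get(rat_of[h], np.nan)) for h in mapped],
            },
            index=pd.Index(mapped, name="gene"),
        )
    panel = merge_panels(panels["parous"], panels["nulliparous"])
    details["parous_panel"] = panels["parous"]
    details["nulliparous_panel"] = panels["nulliparous"]
    return panel, details
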