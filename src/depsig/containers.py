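"""Shared in-memory containers for the DEP-signature pipeline.

All expression values are log2 scale unless a container says otherwise;
count tables are raw non-negative integers.  Genes/probes index the rows,
samples the columns, mirroring the usual transcriptomics layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_CLASSES = ("Positive", "Negative", "Housekeeping", "Endogenous")


@dataclass
class ExprMatrix:
    """Log2 expression matrix (genes x samples) with a sample -> group map.

    ``groups`` assigns every sample column to exactly one experimental
    group (here: parity x treatment, four groups in the rat design).
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_genes(self, genes) -> "ExprMatrix":
        return ExprMatrix(self.values.loc[list(genes)], self.groups.copy())


@dataclass
class ProbeCounts:
    """Raw nCounter-style counts (probes x samples) with probe classes."""

    counts: pd.DataFrame
    probe_class: pd.Series  # per probe, one of PROBE_CLASSES

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if not np.all(vals >= 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        self.probe_class = self.probe_class.reindex(self.counts.index)
        bad = set(self.probe_class.dropna().unique()) - set(PROBE_CLASSES)
        if bad or self.probe_class.isna().any():
            raise ValueError(f"invalid probe classes: {sorted(map(str, bad))}")

    def probes_of(self, cls: str) -> pd.Index:
        return self.counts.index[self.probe_class == cls]

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class NormalizedExpr:
    """Normalized, background-imputed, log2 endogenous expression.

    ``flags`` marks cells that fell below the per-sample background
    threshold and were imputed to threshold/sqrt(2) before the log2.
    ``background`` is on the final (housekeeping-scaled) count scale, so a
    flagged cell equals ``log2(background[s] / sqrt(2))`` exactly.
    """

    values: pd.DataFrame        # log2, Endogenous probes x samples
    flags: pd.DataFrame         # bool, same shape
    pos_factors: pd.Series      # per-sample positive-control scale factor
    hk_factors: pd.Series       # per-sample housekeeping scale factor
    background: pd.Series       # per-sample threshold, final count scale

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def detection_fraction(self) -> pd.Series:
        """Per-gene fraction of samples detected above background."""
        return 1.0 - self.flags.mean(axis=1)


@dataclass
class SignaturePanel:
    """Ordered signature genes with direction, origin and rank score."""

    table: pd.DataFrame  # columns: gene, direction, origin, score, support

    def __post_init__(self) -> None:
        if self.table["gene"].duplicated().any():
            raise ValueError("signature panel has duplicate genes")

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class FactorSolution:
    """Oblique factor-analysis solution for signature-gene expression."""

    loadings: pd.DataFrame      # genes x factors (pattern matrix)
    phi: np.ndarray             # factor correlation matrix (k x k)
    scores: pd.DataFrame        # subjects x factors (regression method)
    assignment: pd.Series = field(default=None)  # gene -> factor label or NA
    rotation: str = "oblimin"

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass
class GeneSetLibrary:
    """Ordered gene-set library (GMT-style): name -> (description, genes)."""

    sets: dict  # insertion-ordered: name -> (description, frozenset of genes)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not g for g in genes):
                raise ValueError(f"gene set {name!r} has empty gene symbols")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str):
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def names(self) -> list[str]:
        return list(self.sets)
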