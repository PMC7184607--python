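"""Readers/writers for on-disk artifacts and pipeline orchestration.

All tables are UTF-8 CSV/TSV with "." decimals and no thousands
separators so a written table re-reads bit-exactly.  Gene-set libraries
use the Broad GMT convention (name, description, genes, tab-separated).
Each pipeline run writes into its own output directory and refuses to
overwrite an existing one, and emits a machine-readable run log with
every effective threshold and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (ExprMatrix, GeneSetLibrary, NormalizedExpr,
                         ProbeCounts)
from .synth import HOUSEKEEPING_GENES


class ParseError(ValueError):
    """A file failed structural validation; the message names the line."""


# ---------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Registry of every analysis threshold, with published defaults."""

    intensity_percentile: float = 30.0
    iqr_keep_frac: float = 0.5
    de_fdr: float = 0.25
    fc_min: float = 1.5
    subsample_k: int = 4
    consensus_min_frac: float = 0.8
    top_k: int = 100
    detection_frac: float = 0.75
    loading_cutoff: float = 0.3
    n_factors: int = 7
    assoc_alpha: float = 0.05
    enrich_fdr: float = 0.05
    paired_fdr: float = 0.05
    background_mode: str = "mean_plus_sd"
    hk_genes: tuple = HOUSEKEEPING_GENES
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        fracs = {
            "iqr_keep_frac": self.iqr_keep_frac,
            "de_fdr": self.de_fdr,
            "consensus_min_frac": self.consensus_min_frac,
            "assoc_alpha": self.assoc_alpha,
            "enrich_fdr": self.enrich_fdr,
            "paired_fdr": self.paired_fdr,
        }
        for name, v in fracs.items():
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.detection_frac < 1:
            raise ValueError("detection_frac must be in [0, 1)")
        if not 0 <= self.intensity_percentile <= 100:
            raise ValueError("intensity_percentile must be in [0, 100]")
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        if not 0 < self.loading_cutoff < 1:
            raise ValueError("loading_cutoff must be in (0, 1)")
        if self.top_k <= 0 or self.subsample_k <= 0 or self.n_factors <= 0:
            raise ValueError("top_k, subsample_k, n_factors must be positive")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hk_genes" in raw:
            raw["hk_genes"] = tuple(raw["hk_genes"])
        return cls(**raw).validate()


# ------------------------------------------------------------- tabular IO

def read_expression_tsv(path, groups: pd.Series | None = None) -> ExprMatrix:
    """Genes x samples TSV (first column = gene ID, header = samples).

    When ``groups`` is omitted the file must carry a '#groups' comment
    line mapping each sample to its group (written by
    :func:`write_expression_tsv`).
    """
    path = Path(path)
    header_groups = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#groups\t"):
            header_groups = first.rstrip("\n").split("\t")[1:]
            skip = 1
        else:
            skip = 0
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        line = list(df.index).index(dup) + 2 + skip
        raise ParseError(f"{path}:{line}: duplicate gene ID {dup!r}")
    bad = df.columns[~df.apply(
        lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise ParseError(f"{path}: non-numeric values in column {bad[0]!r}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing/non-numeric cell in gene {gene!r}")
    if groups is None:
        if header_groups is None:
            raise ParseError(f"{path}: no '#groups' line and no groups given")
        groups = pd.Series(header_groups, index=df.columns)
    df.index.name = None
    return ExprMatrix(df, groups)


def write_expression_tsv(M: ExprMatrix, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#groups\t" + "\t".join(M.groups[c] for c in M.samples) + "\n")
        M.values.to_csv(fh, sep="\t", index_label="gene", lineterminator="\n")


def read_probe_counts(path) -> ProbeCounts:
    """RCC-like table: columns CodeClass, ProbeName, then samples."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("CodeClass", "ProbeName"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    counts = df.set_index("ProbeName").drop(columns=["CodeClass"])
    probe_class = df.set_index("ProbeName")["CodeClass"]
    counts.index.name = None
    probe_class.index.name = None
    probe_class.name = None
    return ProbeCounts(counts, probe_class)


def write_probe_counts(P: ProbeCounts, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    out = P.counts.copy()
    out.insert(0, "CodeClass", P.probe_class)
    out.index.name = "ProbeName"
    out.reset_index().to_csv(path, sep=sep, index=False)


def read_exposure_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "subject_id", "mep_ng_ml", "menopause",
                "tissue", "pair_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df.set_index("sample_id")


def write_exposure_table(df: pd.DataFrame, path) -> None:
    df.reset_index().to_csv(path, index=False)


def read_ortholog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["rat_gene", "human_gene"]:
        raise ParseError(
            f"{path}: expected columns rat_gene, human_gene"
        )
    return df


def write_ortholog_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# --------------------------------------------------------------- GMT IO

def read_gmt(path) -> GeneSetLibrary:
    """Broad-convention GMT: name TAB description TAB gene [TAB gene ...].

    Preserves file order; duplicate genes within a line count once."""
    sets: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: need name, description and >=1 gene"
                )
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: empty gene list")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = (desc, frozenset(genes))
    return GeneSetLibrary(sets)


def write_gmt(lib: GeneSetLibrary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, genes) in lib.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------- orchestration

@dataclass
class RunPaths:
    """Input locations for the pipeline stages actually requested."""

    expression: str | None = None       # rat log2 matrix (+#groups line)
    ortholog_map: str | None = None
    probe_counts: str | None = None     # human raw counts
    exposure: str | None = None
    signature_genes: str | None = None  # plain gene list for human side
    gmt: str | None = None


def run_pipeline(config: PipelineConfig, paths: RunPaths, out_dir,
                 stages=("rat", "human")) -> dict:
    """Execute the configured stages and write result tables + run log.

    The rat side runs filtering -> subsample-consensus signature ->
    ortholog translation -> panel merge.  The human side runs
    normalization -> detection -> quartile-median association (overall
    and by menopausal stratum) -> factor analysis -> enrichment ->
    paired adjacent-vs-tumor tests.  Returns a dict of result tables.
    """
    from . import assoc as assoc_mod
    from . import enrich as enrich_mod
    from . import factors as factors_mod
    from . import nanostring as ns
    from .rat_prep import intensity_filter, iqr_filter
    from .signature import derive_signature

    config.validate()
    out = Path(out_dir)
    if out.exists():
        raise FileExistsError(f"output directory exists: {out}")

    # fail before any computation if a requested stage lacks inputs
    if "rat" in stages and not (paths.expression and paths.ortholog_map):
        raise FileNotFoundError("rat stage needs expression and ortholog_map")
    if "human" in stages and not (paths.probe_counts and paths.exposure):
        raise FileNotFoundError("human stage needs probe_counts and exposure")
    for p in asdict(paths).values():
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(p)

    out.mkdir(parents=True)
    results: dict = {}

    if "rat" in stages:
        M = read_expression_tsv(paths.expression)
        omap = read_ortholog_map(paths.ortholog_map)
        keep = set(intensity_filter(M, config.intensity_percentile))
        kept = [g for g in iqr_filter(M, config.iqr_keep_frac) if g in keep]
        M_f = M.subset_genes(sorted(kept))
        panel, details = derive_signature(
            M_f, omap, fdr=config.de_fdr, fc_min=config.fc_min,
            subsample_k=config.subsample_k,
            min_support=config.consensus_min_frac, top_k=config.top_k,
        )
        panel.table.to_csv(out / "signature_panel.tsv", sep="\t", index=False)
        results["panel"] = panel
        results["filtered_genes"] = kept
        results["rat_details"] = details

    if "human" in stages:
        P = read_probe_counts(paths.probe_counts)
        exposure = read_exposure_table(paths.exposure)
        if paths.signature_genes:
            wanted = [g for g in read_gene_list(paths.signature_genes)
                      if g in set(P.probes_of("Endogenous"))]
            sel = [g for g in P.counts.index
                   if P.probe_class[g] != "Endogenous" or g in set(wanted)]
            P = ProbeCounts(P.counts.loc[sel], P.probe_class[sel])
        N = ns.normalize_run(
            P, hk_genes=config.hk_genes,
            background_mode=config.background_mode,
        )
        detected = ns.detection_filter(N, config.detection_frac)
        values = N.values.loc[detected]

        adj = exposure[exposure["tissue"] == "adjacent"]
        adj_cols = [c for c in values.columns if c in set(adj.index)]
        x = assoc_mod.quartile_median_predictor(
            adj.loc[adj_cols, "mep_ng_ml"].to_numpy()
        )
        V_adj = values[adj_cols]
        assoc_tables = [assoc_mod.gene_assoc(V_adj, x, stratum="all")]
        meno = adj.loc[adj_cols, "menopause"].to_numpy()
        for stratum in ("post", "pre"):
            m = meno == stratum
            if m.sum() >= 4 and np.ptp(x[m]) > 0:
                assoc_tables.append(
                    assoc_mod.gene_assoc(V_adj, x, mask=m, stratum=stratum)
                )
        assoc_table = pd.concat(assoc_tables)
        assoc_table.to_csv(out / "association.tsv", sep="\t",
                           index_label="gene")
        results["association"] = assoc_table

        fa = factors_mod.GeneFactorAnalysis(
            k=config.n_factors, cutoff=config.loading_cutoff
        ).fit(V_adj)
        fa.loadings_.to_csv(out / "loadings.tsv", sep="\t",
                            index_label="gene")
        fa.assignment_.to_csv(out / "factor_assignment.tsv", sep="\t",
                              index_label="gene")
        fa.scores_.to_csv(out / "factor_scores.tsv", sep="\t",
                          index_label="sample")
        fassoc = factors_mod.factor_assoc(fa.solution_(), x)
        fassoc.to_csv(out / "factor_association.tsv", sep="\t",
                      index_label="factor")
        results["factors"] = fa.solution_()
        results["factor_association"] = fassoc

        if paths.gmt:
            lib = read_gmt(paths.gmt)
            sig_factors = fassoc.index[fassoc["p"] < config.assoc_alpha]
            enrich_frames = []
            for f in sig_factors:
                query = fa.assignment_.index[fa.assignment_ == f]
                if len(query) == 0:
                    continue
                tab = enrich_mod.enrich_library(
                    query, lib, universe=detected, fdr=config.enrich_fdr
                )
                tab.insert(0, "factor", f)
                enrich_frames.append(tab)
            if enrich_frames:
                enr = pd.concat(enrich_frames)
                enr.to_csv(out / "enrichment.tsv", sep="\t",
                           index_label="set")
                results["enrichment"] = enr

        tum = exposure[exposure["tissue"] == "tumor"]
        pairs = []
        adj_by_pair = {adj.loc[c, "pair_id"]: c for c in adj_cols}
        for c in tum.index:
            pid = tum.loc[c, "pair_id"]
            if pid in adj_by_pair and c in values.columns:
                pairs.append((adj_by_pair[pid], c))
        if len(pairs) >= 3:
            paired = assoc_mod.paired_wilcoxon(
                values, values, pairs=pairs, fdr=config.paired_fdr
            )
            paired.to_csv(out / "paired_tests.tsv", sep="\t",
                          index_label="gene")
            results["paired"] = paired

        results["normalized"] = N
        results["detected_genes"] = detected

    log = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "inputs": {k: v for k, v in asdict(paths).items() if v},
        "stages": list(stages),
        "quantile_convention": "linear interpolation between order statistics",
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    results["run_log"] = log
    return results
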