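"""Synthetic data generators with known ground truth.

Two study arms are emulated.  The rodent arm is a 2x2 design (parous /
nulliparous x DEP / vehicle, five animals per group) on an already
normalized log2 expression matrix, with a planted, predominantly
down-regulated gene set.  The human arm is an nCounter-style count table
for a breast-tissue cohort: six graded positive spike-ins, eight
low-count negative controls, six stable housekeeping probes and
endogenous probes whose log2 abundances follow a latent block-factor
model.  One block carries a planted negative slope on the quartile-median
ln-MEP predictor, and a subset of subjects carries a paired tumor column
with planted adjacent-vs-tumor shifts.

Every generator is deterministic given its seed, and returns the planted
truth alongside the data so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExprMatrix, GeneSetLibrary, ProbeCounts

RAT_GROUPS = (
    "parous_dep",
    "parous_vehicle",
    "nulliparous_dep",
    "nulliparous_vehicle",
)

# Default housekeeping panel used on the human code-set.
HOUSEKEEPING_GENES = ("CLTC", "GAPDH", "GUSB", "HPRT1", "PGK1", "TUBB")

# Positive spike-ins follow the usual 4-fold concentration ladder.
_POS_LADDER = np.array([30000.0, 7500.0, 1875.0, 468.75, 117.19, 29.3])
_NEG_MEAN = 8.0            # Poisson mean of negative controls (per lane unit)
_HK_LOG2 = np.array([11.0, 10.5, 10.0, 9.5, 10.2, 10.8])
_LANE_SIGMA = 0.15         # lognormal sigma of per-sample lane scale


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass
class RatSimConfig:
    """Configuration of the synthetic rodent microarray experiment.

    Defaults mirror the study design being emulated: five animals per
    group in a parity x treatment layout, with a planted gene set
    down-regulated by treatment at one log2 unit (2-fold) against a
    residual log2 SD of 0.3.
    """

    n_per_group: int = 5
    n_genes: int = 500
    n_planted_down: int = 50
    planted_log2fc: float = -1.0
    noise_sd: float = 0.3
    parity_groups: tuple = ("parous", "nulliparous")
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("need >=2 animals per group")
        if self.n_genes <= 0 or self.n_planted_down < 0:
            raise ConfigurationError("gene counts must be positive")
        if self.n_planted_down > self.n_genes:
            raise ConfigurationError("more planted genes than genes")
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd must be > 0")
        bad = set(self.parity_groups) - {"parous", "nulliparous"}
        if bad:
            raise ConfigurationError(f"unknown parity groups: {sorted(bad)}")


@dataclass
class CohortSimConfig:
    """Configuration of the synthetic human breast-tissue cohort.

    ``assoc_block`` names the latent-factor block whose genes carry the
    planted slope ``assoc_beta`` (log2 expression per unit of the
    quartile-median ln-MEP predictor).  ``tumor_shift`` is the planted
    adjacent-minus-tumor log2 shift per endogenous gene; by default the
    association block shifts down (-0.5) and block 0 up (+0.5).
    """

    n_subjects: int = 294
    n_genes: int = 107
    n_factors: int = 7
    block_corr: float = 0.7
    frac_postmenopausal: float = 189 / 294
    mep_logmean: float = 4.5     # ln ng/mL
    mep_logsd: float = 1.1
    assoc_block: int = 1
    assoc_beta: float = -0.15
    tumor_shift: np.ndarray | None = None
    frac_paired: float = 243 / 294
    seed: int = 0
    # Count-model nuisance parameters (not part of the planted truth).
    gene_sd: float = 0.6          # total log2 SD of an endogenous gene
    baseline_log2: tuple = (6.0, 10.0)
    frac_low_expressed: float = 0.1
    low_baseline_log2: float = 2.5
    pair_noise_sd: float = 0.2

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_genes <= 0 or self.n_factors <= 0:
            raise ConfigurationError("sizes must be positive")
        if not 0 < self.block_corr < 1:
            raise ConfigurationError("block_corr must be in (0,1)")
        if not 0 <= self.frac_postmenopausal <= 1:
            raise ConfigurationError("frac_postmenopausal must be in [0,1]")
        if not 0 <= self.assoc_block < self.n_factors:
            raise ConfigurationError("assoc_block must index a factor block")
        if not 0 < self.frac_paired <= 1:
            raise ConfigurationError("frac_paired must be in (0,1]")
        if round(self.frac_paired * self.n_subjects) < 2:
            raise ConfigurationError("fewer than 2 paired subjects")


def gen_rat_experiment(cfg: RatSimConfig):
    """Simulate the four-group rodent experiment.

    Returns ``(ExprMatrix, planted_genes)``.  Planted genes receive
    ``planted_log2fc`` in both parity arms' treated groups, so the
    noise-free treated-minus-control group mean equals the configured
    fold change exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    width = len(str(cfg.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    planted = genes[: cfg.n_planted_down]

    columns, labels = [], []
    for parity in cfg.parity_groups:
        for treat in ("dep", "vehicle"):
            group = f"{parity}_{treat}"
            for i in range(cfg.n_per_group):
                columns.append(f"{group}_{i + 1}")
                labels.append(group)
    groups = pd.Series(labels, index=columns)

    baseline = rng.normal(7.0, 1.5, size=cfg.n_genes)
    mat = np.tile(baseline[:, None], (1, len(columns)))
    treated = np.array([g.endswith("_dep") for g in labels])
    mat[: cfg.n_planted_down, treated] += cfg.planted_log2fc
    mat += rng.normal(0.0, cfg.noise_sd, size=mat.shape)

    values = pd.DataFrame(mat, index=genes, columns=columns)
    return ExprMatrix(values, groups), planted


def _quartile_median_x(ln_mep: np.ndarray) -> np.ndarray:
    # local copy of the predictor construction to keep the generator's
    # planted slope defined on the same scale the analysis uses
    from .assoc import quartile_median_predictor

    return quartile_median_predictor(np.exp(ln_mep))


def gen_nanostring_cohort(cfg: CohortSimConfig):
    """Simulate the nCounter cohort: counts, exposure table, and truth.

    Returns ``(ProbeCounts, exposure: DataFrame, truth: dict)``.  Truth
    holds the block assignment of every endogenous gene, the planted
    block index, the per-gene slope on the quartile-median ln-MEP
    predictor, the tumor shifts, and the noiseless latent log2 matrix.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n, g, k = cfg.n_subjects, cfg.n_genes, cfg.n_factors
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    adj_cols = [f"{s}_adj" for s in subjects]

    mep = np.exp(rng.normal(cfg.mep_logmean, cfg.mep_logsd, size=n))
    postmeno = rng.random(n) < cfg.frac_postmenopausal
    x = _quartile_median_x(np.log(mep))
    x_c = x - x.mean()

    width = len(str(g))
    genes = [f"SIG{i + 1:0{width}d}" for i in range(g)]
    block = np.arange(g) % k  # round-robin block membership

    a = cfg.gene_sd * np.sqrt(cfg.block_corr)       # shared loading
    u = cfg.gene_sd * np.sqrt(1.0 - cfg.block_corr)  # unique SD
    factors = rng.normal(size=(k, n))
    # residualize factor scores against the predictor so the planted
    # per-gene slope is exact in the noiseless latent matrix (the
    # analogue of the rat generator's exact planted fold change)
    xq = x_c / np.sqrt(x_c @ x_c)

    def _orthogonal_noise(shape):
        e = rng.normal(size=shape)
        e -= np.outer(e @ xq, xq)
        e -= e.mean(axis=1, keepdims=True)
        e /= e.std(axis=1, keepdims=True)
        return e

    factors = _orthogonal_noise((k, n))
    latent = a * factors[block, :] + u * _orthogonal_noise((g, n))

    beta = np.where(block == cfg.assoc_block, cfg.assoc_beta, 0.0)
    latent += beta[:, None] * x_c[None, :]

    baseline = rng.uniform(*cfg.baseline_log2, size=g)
    n_low = int(round(cfg.frac_low_expressed * g))
    if n_low:
        low_idx = rng.choice(g, size=n_low, replace=False)
        baseline[low_idx] = cfg.low_baseline_log2
    latent_adj = baseline[:, None] + latent

    if cfg.tumor_shift is None:
        shift = np.zeros(g)
        shift[block == cfg.assoc_block] = -0.5
        shift[block == (cfg.assoc_block + 1) % k] = 0.5
    else:
        shift = np.asarray(cfg.tumor_shift, dtype=float)
        if shift.shape != (g,):
            raise ConfigurationError("tumor_shift must have one entry per gene")

    n_paired = int(round(cfg.frac_paired * n))
    paired_idx = np.sort(rng.choice(n, size=n_paired, replace=False))
    latent_tum = (
        latent_adj[:, paired_idx]
        - shift[:, None]
        + rng.normal(0.0, cfg.pair_noise_sd, size=(g, n_paired))
    )
    tum_cols = [f"{subjects[i]}_tum" for i in paired_idx]

    cols = adj_cols + tum_cols
    lane = np.exp(rng.normal(0.0, _LANE_SIGMA, size=len(cols)))

    def _counts(mean_mat: np.ndarray) -> np.ndarray:
        return rng.poisson(np.clip(mean_mat, 0.0, None) * lane[None, :])

    endo = _counts(2.0 ** np.hstack([latent_adj, latent_tum]))
    pos = _counts(np.tile(_POS_LADDER[:, None], (1, len(cols))))
    neg = _counts(np.full((8, len(cols)), _NEG_MEAN))
    hk = _counts(np.tile((2.0 ** _HK_LOG2)[:, None], (1, len(cols))))

    pos_names = [f"POS_{c}" for c in "ABCDEF"]
    neg_names = [f"NEG_{c}" for c in "ABCDEFGH"]
    counts = pd.DataFrame(
        np.vstack([pos, neg, hk, endo]),
        index=pos_names + neg_names + list(HOUSEKEEPING_GENES) + genes,
        columns=cols,
    )
    probe_class = pd.Series(
        ["Positive"] * 6 + ["Negative"] * 8 + ["Housekeeping"] * 6
        + ["Endogenous"] * g,
        index=counts.index,
    )

    exposure = pd.DataFrame(
        {
            "subject_id": subjects + [subjects[i] for i in paired_idx],
            "sample_id": cols,
            "mep_ng_ml": np.concatenate([mep, mep[paired_idx]]),
            "menopause": np.concatenate(
                [
                    np.where(postmeno, "post", "pre"),
                    np.where(postmeno[paired_idx], "post", "pre"),
                ]
            ),
            "tissue": ["adjacent"] * n + ["tumor"] * n_paired,
            "pair_id": subjects + [subjects[i] for i in paired_idx],
        }
    ).set_index("sample_id")

    truth = {
        "genes": genes,
        "block": pd.Series(block, index=genes),
        "assoc_block": cfg.assoc_block,
        "planted_genes": [genes[i] for i in np.where(block == cfg.assoc_block)[0]],
        "beta": pd.Series(beta, index=genes),
        "tumor_shift": pd.Series(shift, index=genes),
        "latent_adj": pd.DataFrame(latent_adj, index=genes, columns=adj_cols),
        "predictor": pd.Series(x, index=adj_cols),
        "neg_mean": _NEG_MEAN,
    }
    return ProbeCounts(counts, probe_class), exposure, truth


def gen_ortholog_map(rat_genes, mapped_fraction: float, seed: int = 0,
                     prefix: str = "HS_") -> pd.DataFrame:
    """Map a deterministic random subset of rat genes to human symbols.

    Exactly ``round(mapped_fraction * len(rat_genes))`` genes appear in
    the two-column map; unmapped genes are simply absent.
    """
    if not 0 < mapped_fraction <= 1:
        raise ConfigurationError("mapped_fraction must be in (0,1]")
    rat_genes = list(rat_genes)
    rng = np.random.default_rng(seed)
    n_map = int(round(mapped_fraction * len(rat_genes)))
    chosen = sorted(rng.choice(len(rat_genes), size=n_map, replace=False))
    mapped = [rat_genes[i] for i in chosen]
    return pd.DataFrame(
        {"rat_gene": mapped, "human_gene": [f"{prefix}{g.upper()}" for g in mapped]}
    )


def gen_geneset_library(universe, n_sets: int, set_size_range=(10, 50),
                        planted_set=None, seed: int = 0,
                        planted_name: str = "PLANTED_TF") -> GeneSetLibrary:
    """Random TF-target-style library containing ``planted_set`` verbatim."""
    universe = list(universe)
    rng = np.random.default_rng(seed)
    lo, hi = set_size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ConfigurationError("set_size_range incompatible with universe")

    sets: dict = {}
    if planted_set is not None:
        planted_set = frozenset(planted_set)
        if not planted_set <= set(universe):
            raise ConfigurationError("planted_set must be within the universe")
        sets[planted_name] = ("planted truth set", planted_set)
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"RANDOM_TF_{i + 1:03d}"] = (
            "random set",
            frozenset(universe[j] for j in members),
        )
    return GeneSetLibrary(sets)
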