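"""nCounter-style count normalization and detection filtering.

Three sequential steps, in the narrative order of the assay protocol:

1. **Positive-control normalization** — each sample is scaled so its
   geometric mean of the six spike-in probes equals the grand geometric
   mean across samples.
2. **Background imputation** — the per-sample background threshold is
   the mean plus two standard deviations (n-1 denominator) of the
   scaled negative-control counts; endogenous counts below it are
   deemed unexpressed and replaced by threshold / sqrt(2), flagged.
3. **Housekeeping normalization** — samples are rescaled so the
   geometric mean of the housekeeping genes (default CLTC, GAPDH, GUSB,
   HPRT1, PGK1, TUBB) is constant, then everything is log2 transformed.

The reported per-sample background is carried onto the final
(housekeeping-scaled) count scale, so every flagged cell equals
``log2(background / sqrt(2))`` for its sample exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import NormalizedExpr, ProbeCounts
from .synth import HOUSEKEEPING_GENES

__all__ = [
    "background_threshold",
    "NanoStringNormalizer",
    "normalize_run",
    "detection_filter",
]


def background_threshold(neg_counts: pd.DataFrame,
                         n_sd: float = 2.0,
                         mode: str = "mean_plus_sd") -> pd.Series:
    """Per-sample background from negative-control counts.

    ``mean_plus_sd`` (default) is mean + n_sd * sd, the usual nCounter
    background convention for "below two standard deviations of the
    mean of negative control probes"; ``mean_minus_sd`` is the literal
    reading (mean - n_sd * sd), exposed as a switch.
    """
    if neg_counts.shape[0] < 2:
        raise ValueError("need >=2 negative-control probes")
    mean = neg_counts.mean(axis=0)
    sd = neg_counts.std(axis=0, ddof=1)
    if mode == "mean_plus_sd":
        return mean + n_sd * sd
    if mode == "mean_minus_sd":
        return mean - n_sd * sd
    raise ValueError(f"unknown background mode: {mode!r}")


def _geomean(frame: pd.DataFrame) -> pd.Series:
    vals = frame.to_numpy(dtype=float)
    if np.any(vals <= 0):
        bad = frame.columns[(vals <= 0).any(axis=0)][0]
        raise ValueError(f"non-positive count in geometric mean (sample {bad})")
    return pd.Series(np.exp(np.log(vals).mean(axis=0)), index=frame.columns)


class NanoStringNormalizer(BaseEstimator, TransformerMixin):
    """Transformer wrapping the three-step normalization.

    ``fit`` learns nothing across datasets (all factors are per-run);
    it exists so the class composes with sklearn pipelines.  Fitted
    attributes (``pos_factors_`` etc.) are those of the last run.
    """

    def __init__(self, hk_genes=HOUSEKEEPING_GENES, n_sd: float = 2.0,
                 background_mode: str = "mean_plus_sd"):
        self.hk_genes = hk_genes
        self.n_sd = n_sd
        self.background_mode = background_mode

    def fit(self, P: ProbeCounts, y=None):
        self.result_ = self._normalize(P)
        self.pos_factors_ = self.result_.pos_factors
        self.hk_factors_ = self.result_.hk_factors
        self.background_ = self.result_.background
        return self

    def transform(self, P: ProbeCounts) -> pd.DataFrame:
        return self._normalize(P).values

    def fit_transform(self, P: ProbeCounts, y=None) -> pd.DataFrame:
        return self.fit(P).result_.values

    def _normalize(self, P: ProbeCounts) -> NormalizedExpr:
        counts = P.counts.astype(float)

        # step 1: positive-control scaling
        pos = counts.loc[P.probes_of("Positive")]
        if pos.empty:
            raise ValueError("no Positive probes")
        pos_gm = _geomean(pos)
        grand = float(np.exp(np.log(pos_gm).mean()))
        pos_factors = grand / pos_gm
        scaled = counts * pos_factors

        # step 2: background threshold and imputation on scaled counts
        neg = scaled.loc[P.probes_of("Negative")]
        thr = background_threshold(neg, self.n_sd, self.background_mode)
        endo = scaled.loc[P.probes_of("Endogenous")]
        flags = endo.lt(thr, axis=1)
        imputed = endo.mask(flags, thr / np.sqrt(2.0), axis=1)

        # step 3: housekeeping scaling, then log2
        hk_genes = list(self.hk_genes)
        missing = set(hk_genes) - set(P.probes_of("Housekeeping"))
        if missing:
            raise ValueError(
                f"housekeeping genes absent from run: {sorted(missing)}"
            )
        hk = scaled.loc[hk_genes]
        hk_gm = _geomean(hk)
        if (hk_gm <= 0).any():
            bad = hk_gm.index[hk_gm <= 0][0]
            raise ValueError(f"zero housekeeping geometric mean in {bad}")
        hk_grand = float(np.exp(np.log(hk_gm).mean()))
        hk_factors = hk_grand / hk_gm

        final = imputed * hk_factors
        background_final = thr * hk_factors
        # re-impute on the final scale so flagged cells equal
        # background/sqrt(2) bit-exactly after the log2
        final = final.mask(flags, background_final / np.sqrt(2.0), axis=1)
        with np.errstate(divide="ignore"):
            values = np.log2(final)

        return NormalizedExpr(
            values=values,
            flags=flags,
            pos_factors=pos_factors,
            hk_factors=hk_factors,
            background=background_final,
        )


def normalize_run(P: ProbeCounts, hk_genes=HOUSEKEEPING_GENES,
                  n_sd: float = 2.0,
                  background_mode: str = "mean_plus_sd") -> NormalizedExpr:
    """Run the three-step normalization; see :class:`NanoStringNormalizer`."""
    return NanoStringNormalizer(hk_genes, n_sd, background_mode)._normalize(P)


def detection_filter(N: NormalizedExpr, min_frac: float = 0.75) -> list[str]:
    """Genes detected above background in strictly more than
    ``min_frac`` of samples."""
    if not 0 <= min_frac < 1:
        raise ValueError("min_frac must be in [0, 1)")
    det = N.detection_fraction()
    return list(det.index[det > min_frac])
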