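import numpy as np
import pandas as pd
import pytest

from depsig.containers import ExprMatrix
from depsig.nanostring import normalize_run
from depsig.synth import (CohortSimConfig, RatSimConfig,
                          gen_nanostring_cohort, gen_rat_experiment)


@pytest.fixture(scope="session")
def rat_sim():
    """Default rodent simulation: 500 genes, 50 planted down 2-fold."""
    M, planted = gen_rat_experiment(RatSimConfig(seed=0))
    return M, planted


@pytest.fixture(scope="session")
def cohort_sim():
    """Default human cohort: 294 adjacent tissues, 243 paired tumors."""
    return gen_nanostring_cohort(CohortSimConfig(seed=0))


@pytest.fixture(scope="session")
def postmeno_cohort():
    """All-postmenopausal cohort of 189 subjects (stratified analog)."""
    cfg = CohortSimConfig(n_subjects=189, frac_postmenopausal=1.0, seed=0)
    return gen_nanostring_cohort(cfg)


@pytest.fixture(scope="session")
def normalized_cohort(cohort_sim):
    P, exposure, truth = cohort_sim
    return normalize_run(P), exposure, truth


def make_expr(values, groups):
    """Small helper to build an ExprMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    genes = [f"g{i + 1}" for i in range(values.shape[0])]
    cols = [f"s{j + 1}" for j in range(values.shape[1])]
    return ExprMatrix(
        pd.DataFrame(values, index=genes, columns=cols),
        pd.Series(list(groups), index=cols),
    )
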