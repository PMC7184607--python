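"""Quartile-median predictor, per-gene GLM, AR gating, paired Wilcoxon."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depsig.assoc import (QuartileMedianBinner, ar_positive_mask, gene_assoc,
                          paired_wilcoxon, quartile_median_predictor)


def wilcoxon_oracle(diffs):
    """Exact two-sided signed-rank p by enumerating all sign vectors."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2
    count = 0
    for signs in product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2 ** n


class TestQuartileMedianPredictor:
    def test_equal_spacing_example(self):
        # ln-MEP 1..8: quartiles {1,2},{3,4},{5,6},{7,8} with medians
        # 1.5, 3.5, 5.5, 7.5
        x = quartile_median_predictor(np.exp(np.arange(1.0, 9.0)))
        assert np.allclose(x, [1.5, 1.5, 3.5, 3.5, 5.5, 5.5, 7.5, 7.5])

    def test_constant_exposure_gives_constant_predictor(self):
        x = quartile_median_predictor([5.0] * 8)
        assert np.ptp(x) == 0

    def test_at_most_four_levels_each_a_group_median(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            raw = rng.lognormal(4, 1, size=8)
            x = quartile_median_predictor(raw)
            ln = np.sort(np.log(raw))
            expect = {np.median(ln[i:i + 2]) for i in range(0, 8, 2)}
            assert set(np.round(x, 12)) <= set(np.round(sorted(expect), 12))
            assert len(np.unique(x)) <= 4

    def test_boundary_goes_to_lower_quartile(self):
        vals = np.exp([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        binner = QuartileMedianBinner().fit(vals)
        q1 = binner.cuts_[0]
        assert binner.transform([np.exp(q1)])[0] == binner.medians_[0]

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            quartile_median_predictor([1.0, -2.0, 3.0, 4.0])

    def test_needs_four_subjects(self):
        with pytest.raises(ValueError):
            quartile_median_predictor([1.0, 2.0, 3.0])


class TestGeneAssoc:
    def _frame(self, rows):
        arr = np.atleast_2d(np.asarray(rows, dtype=float))
        return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                            columns=[f"s{j}" for j in range(arr.shape[1])])

    def test_closed_form_slope(self):
        res = gene_assoc(self._frame([2, 1, 4, 3]), [1, 2, 3, 4])
        assert res["beta"].iloc[0] == pytest.approx(0.6)

    def test_constant_response(self):
        res = gene_assoc(self._frame([5, 5, 5, 5]), [1, 2, 3, 4])
        assert res["beta"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_perfect_fit_flagged(self):
        res = gene_assoc(self._frame([2, 4, 6, 8]), [1, 2, 3, 4])
        assert res["beta"].iloc[0] == pytest.approx(2.0)
        assert res["p"].iloc[0] == 0.0
        assert bool(res["perfect_fit"].iloc[0])

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            gene_assoc(self._frame([1, 2, 3, 4]), [2, 2, 2, 2])

    def test_stratum_mask_and_n(self):
        Y = self._frame(np.arange(12).reshape(2, 6))
        mask = np.array([1, 1, 1, 1, 0, 0], dtype=bool)
        res = gene_assoc(Y, [1, 2, 3, 4, 5, 6], mask=mask, stratum="post")
        assert (res["n"] == 4).all()
        assert (res["stratum"] == "post").all()

    def test_matches_statsmodels_on_random_designs(self):
        """Slope and p agree with the reference OLS implementation."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 15))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + rng.normal() * x
            res = gene_assoc(self._frame(y), x)
            ref = sm.OLS(y, sm.add_constant(x)).fit()
            assert res["beta"].iloc[0] == pytest.approx(ref.params[1],
                                                        abs=1e-10)
            assert res["p"].iloc[0] == pytest.approx(ref.pvalues[1],
                                                     abs=1e-10)

    def test_stratum_homogeneous_cohort_equals_stratum_analysis(self):
        rng = np.random.default_rng(3)
        Y = self._frame(rng.normal(size=(5, 30)))
        x = rng.normal(size=30)
        full = gene_assoc(Y, x, stratum="all")
        masked = gene_assoc(Y, x, mask=np.ones(30, bool), stratum="post")
        assert np.allclose(full["beta"], masked["beta"])
        assert np.allclose(full["p"], masked["p"])


class TestARPositive:
    def test_single_low_outlier(self):
        vals = [0.0] + [10.0] * 8
        mask = ar_positive_mask(vals)
        assert mask.sum() == 8
        assert not mask[0]

    def test_no_low_outliers_keeps_all(self):
        assert ar_positive_mask([1, 2, 3, 4, 5]).all()

    def test_uniform_1_to_100_all_positive(self):
        # Q1 25.75, Q3 75.25, fence 25.75 - 1.5*49.5 < 1
        assert ar_positive_mask(np.arange(1.0, 101.0)).all()

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            ar_positive_mask([1, 2, 3, 4])


class TestPairedWilcoxon:
    def _tables(self, diffs):
        diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
        cols = [f"p{j}" for j in range(diffs.shape[1])]
        genes = [f"g{i}" for i in range(diffs.shape[0])]
        adj = pd.DataFrame(diffs, index=genes, columns=cols)
        tum = pd.DataFrame(np.zeros_like(diffs), index=genes, columns=cols)
        return adj, tum

    def test_three_positive_diffs(self):
        adj, tum = self._tables([[1, 2, 3]])
        res = paired_wilcoxon(adj, tum)
        assert res["p"].iloc[0] == pytest.approx(0.25)
        assert res["direction"].iloc[0] == 1

    def test_symmetric_diffs_p_one(self):
        adj, tum = self._tables([[-1, 1, 2, -2]])
        assert paired_wilcoxon(adj, tum)["p"].iloc[0] == pytest.approx(1.0)

    def test_too_few_nonzero_pairs_reported(self):
        adj, tum = self._tables([[1, 0, 0, 0]])
        res = paired_wilcoxon(adj, tum)
        assert np.isnan(res["p"].iloc[0])
        assert "nonzero" in res["note"].iloc[0]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50).filter(lambda v: v != 0),
                    min_size=3, max_size=10, unique_by=abs))
    def test_exact_p_matches_enumeration(self, diffs):
        adj, tum = self._tables([diffs])
        res = paired_wilcoxon(adj, tum)
        assert res["p"].iloc[0] == pytest.approx(wilcoxon_oracle(diffs),
                                                 abs=1e-10)

    def test_large_n_planted_shift_detected(self):
        detected = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            adj, tum = self._tables([rng.normal(1.0, 1.0, size=30)])
            if paired_wilcoxon(adj, tum)["p"].iloc[0] < 0.01:
                detected += 1
        assert detected >= 9

    def test_bh_across_genes(self):
        rng = np.random.default_rng(5)
        diffs = rng.normal(0, 1, size=(20, 12))
        diffs[0] += 3.0
        adj, tum = self._tables(diffs)
        res = paired_wilcoxon(adj, tum, fdr=0.05)
        assert (res["q"] >= res["p"] - 1e-12).all()
        assert bool(res["significant"].iloc[0])
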