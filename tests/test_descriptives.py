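"""Classical test theory statistics and maximal-reliability weighting."""

import numpy as np
import pandas as pd
import pytest

import gad7irt as g
from gad7irt.descriptives import (
    _covmax,
    _fit_one_factor,
    item_descriptives,
    item_restscore,
    max_reliability_weights,
    scalability,
)


def matrix(scores, **kwargs):
    scores = np.asarray(scores)
    return g.ItemResponseMatrix(
        scores=scores, missing_mask=np.zeros_like(scores, dtype=bool), **kwargs
    )


class TestItemDescriptives:
    def test_hand_computed_toy(self):
        data = matrix([[0, 1, 2], [1, 1, 3], [2, 2, 1], [3, 2, 0]])
        table, corr = item_descriptives(data)
        assert np.allclose(table["mean"], [1.5, 1.5, 1.5])
        # hand: sd of column 0 = sqrt(sum((x-1.5)^2)/3) = sqrt(5/3)
        assert table["sd"].iloc[0] == pytest.approx(np.sqrt(5 / 3))
        r01 = np.corrcoef([0, 1, 2, 3], [1, 1, 2, 2])[0, 1]
        assert corr.iloc[0, 1] == pytest.approx(r01)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_identical_columns_correlate_one(self):
        col = np.array([0, 1, 2, 3, 1, 2])
        data = matrix(np.column_stack([col, col, 3 - col]))
        _, corr = item_descriptives(data)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert corr.iloc[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_item_flagged_undefined(self):
        data = matrix([[0, 1, 1], [0, 2, 1], [0, 3, 2], [0, 0, 3]])
        table, corr = item_descriptives(data)
        assert np.isnan(corr.iloc[0, 1]) and np.isnan(corr.iloc[0, 2])
        assert corr.iloc[0, 0] == 1.0  # diagonal stays defined

    def test_pairwise_complete_handling(self):
        scores = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
        mask = np.zeros_like(scores, dtype=bool)
        mask[3, 1] = True
        data = g.ItemResponseMatrix(scores=scores, missing_mask=mask)
        table, corr = item_descriptives(data)
        assert table.loc[data.item_labels[1], "n_obs"] == 3
        expected = np.corrcoef([0, 1, 2], [1, 2, 3])[0, 1]
        assert corr.iloc[0, 1] == pytest.approx(expected)


class TestRestscore:
    def test_parallel_binary_items(self):
        col = np.array([0, 0, 1, 1, 0, 1, 1, 0])
        data = matrix(np.column_stack([col, col, col]), n_categories=2)
        r = item_restscore(data)
        assert np.allclose(r, 1.0)

    def test_matches_bruteforce_toy(self):
        scores = np.array(
            [[0, 1, 2], [1, 1, 3], [2, 2, 1], [3, 2, 0], [1, 0, 2]]
        )
        data = matrix(scores)
        r = item_restscore(data)
        for j in range(3):
            rest = np.delete(scores, j, axis=1).sum(axis=1)
            assert r.iloc[j] == pytest.approx(
                np.corrcoef(scores[:, j], rest)[0, 1]
            )

    def test_tracks_discrimination_ordering(self, big_sample, gad7_params):
        # items 2 and 5 have similar difficulty ordering but lambda 3.55 vs
        # 1.69; the restscore correlation must rank them the same way
        data, _, _ = big_sample
        r = item_restscore(data)
        assert r.iloc[1] > r.iloc[4]
        assert r.iloc[1] > r.iloc[5]


class TestScalability:
    def test_item_with_itself_is_one(self, rng):
        x = rng.integers(0, 4, 200).astype(float)
        assert np.cov(x, x, ddof=1)[0, 1] / _covmax(x, x) == pytest.approx(1.0)

    def test_independent_items_near_zero(self, rng):
        n = 50_000
        data = matrix(rng.integers(0, 4, size=(n, 3)))
        pairs, hi = scalability(data)
        assert np.all(np.abs(pairs.to_numpy()[np.triu_indices(3, 1)]) < 0.02)
        assert np.all(np.abs(hi) < 0.02)

    def test_bruteforce_coupling_oracle(self):
        # 6-respondent toy: covmax from explicitly sorted marginals
        x = np.array([0.0, 1, 1, 2, 3, 3])
        y = np.array([1.0, 0, 2, 2, 3, 1])
        data = matrix(np.column_stack([x, y, (x + y) % 4]))
        pairs, _ = scalability(data)
        covmax_xy = np.cov(np.sort(x), np.sort(y), ddof=1)[0, 1]
        expected = np.cov(x, y, ddof=1)[0, 1] / covmax_xy
        assert pairs.iloc[0, 1] == pytest.approx(expected)

    def test_hij_bounded_by_one(self, big_sample):
        data, _, _ = big_sample
        pairs, hi = scalability(data)
        vals = pairs.to_numpy()[np.triu_indices(7, 1)]
        assert np.all(vals <= 1.0 + 1e-12)
        assert np.all(hi > 0)  # monotone unidimensional data scales

    def test_degenerate_marginal_flagged(self):
        data = matrix([[0, 1], [0, 2], [0, 0]])
        pairs, hi = scalability(data)
        assert np.isnan(pairs.iloc[0, 1])
        assert np.isnan(hi.iloc[0])


class TestMaxReliability:
    def test_parallel_items_equal_weights(self, rng):
        # equal loadings + equal uniquenesses => equal weights and the
        # closed-form reliability of a parallel test
        lam, psi, j, n = 1.0, 0.8, 5, 40_000
        f = rng.standard_normal(n)
        x = lam * f[:, None] + np.sqrt(psi) * rng.standard_normal((n, j))
        est_l, est_p, heywood = _fit_one_factor(np.cov(x, rowvar=False))
        assert not heywood
        assert np.allclose(est_l, est_l.mean(), atol=0.03)
        s = np.sum(est_l**2 / est_p)
        expected = (j * lam**2 / psi) / (1 + j * lam**2 / psi)
        assert s / (1 + s) == pytest.approx(expected, abs=0.01)

    def test_weight_ratios_recovered(self, rng):
        lam = np.array([0.9, 1.4, 0.6, 1.0])
        psi = np.array([0.5, 0.3, 0.9, 0.6])
        n = 60_000
        f = rng.standard_normal(n)
        x = lam * f[:, None] + np.sqrt(psi) * rng.standard_normal((n, 4))
        est_l, est_p, _ = _fit_one_factor(np.cov(x, rowvar=False))
        est_w = est_l / est_p
        truth = lam / psi
        assert np.allclose(est_w / est_w[0], truth / truth[0], rtol=0.05)

    def test_weighted_beats_unit_weights(self, big_sample):
        # maximality: under the fitted factor model the lambda/psi composite
        # is at least as reliable as the unit-weight sum score
        data, _, _ = big_sample
        from gad7irt.descriptives import _pairwise_stats

        _, cov, _ = _pairwise_stats(data)
        lam, psi, _ = _fit_one_factor(cov.to_numpy())

        def model_reliability(w):
            true_var = (w @ lam) ** 2
            return true_var / (true_var + np.sum(w**2 * psi))

        assert model_reliability(lam / psi) >= model_reliability(
            np.ones(7)
        ) - 1e-12

    def test_ci_covers_truth(self, rng):
        # scaled-down coverage run: 10 replicates at n=800, B=200
        lam = np.array([0.8, 1.1, 0.9, 1.0, 0.7, 0.6, 0.9])
        psi = np.array([0.6, 0.4, 0.5, 0.5, 0.7, 0.8, 0.55])
        s = np.sum(lam**2 / psi)
        truth = s / (1 + s)
        hits = 0
        for rep in range(10):
            n = 800
            f = rng.standard_normal(n)
            x = lam * f[:, None] + np.sqrt(psi) * rng.standard_normal((n, 7))
            data = g.ItemResponseMatrix(
                scores=np.clip(np.round(x - x.mean() + 1.5), 0, 3).astype(int),
                missing_mask=np.zeros((n, 7), dtype=bool),
            )
            # use the continuous generator directly via a frame-level fit:
            cov = np.cov(x, rowvar=False)
            bl, bp, _ = _fit_one_factor(cov)
            del data
            boots = np.empty(200)
            for b in range(200):
                idx = rng.integers(0, n, n)
                l2, p2, _ = _fit_one_factor(np.cov(x[idx], rowvar=False))
                sb = np.sum(l2**2 / p2)
                boots[b] = sb / (1 + sb)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            hits += lo <= truth <= hi
        assert hits >= 8

    def test_describe_bundle(self, big_sample):
        data, _, _ = big_sample
        report = g.describe(data, n_bootstrap=50, seed=0)
        assert report.item_table.shape[0] == 7
        assert report.max_reliability > 0.8
        lo, hi = report.reliability_ci
        assert lo <= report.max_reliability <= hi
        assert report.weights == pytest.approx(
            report.weights, abs=0
        )  # finite
        assert np.all(np.isfinite(report.weights))
        # the most discriminating item (2) outweighs the least (5 or 6)
        assert report.weights[1] > min(report.weights[4], report.weights[5])
        assert "Composite reliability" in report.to_text()
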