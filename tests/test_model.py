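"""Graded response model mathematics: probabilities, information, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import gad7irt as g
from gad7irt.model import DEFAULT_GRID, cumulative_probabilities


class TestCategoryProbabilities:
    @pytest.mark.parametrize("theta", [-4.0, -1.0, 0.0, 0.7, 3.0])
    def test_probabilities_sum_to_one(self, gad7_params, theta):
        for j in range(gad7_params.n_items):
            p = g.category_probabilities(gad7_params, j, theta)
            assert p.shape == (4,)
            assert np.all(p >= 0) and np.all(p <= 1)
            assert np.isclose(p.sum(), 1.0)

    def test_logistic_midpoint(self, gad7_params):
        # at theta = tau_c / lambda the cumulative probability is exactly 1/2
        for j in range(gad7_params.n_items):
            for c in range(3):
                theta = gad7_params.thresholds[j, c] / gad7_params.discrimination[j]
                star = cumulative_probabilities(gad7_params, j, np.array(theta))
                assert star[c] == pytest.approx(0.5)

    def test_shipped_item1_at_zero(self, gad7_params):
        # P(X>=1 | theta=0) = 1/(1+e^-0.46) for the first item
        p = g.category_probabilities(gad7_params, 0, 0.0)
        assert 1.0 - p[0] == pytest.approx(1 / (1 + np.exp(-0.46)), abs=1e-9)
        assert 1.0 - p[0] == pytest.approx(0.613, abs=5e-4)

    def test_infinite_theta_limits(self, gad7_params):
        lo = g.category_probabilities(gad7_params, 0, -np.inf)
        hi = g.category_probabilities(gad7_params, 0, np.inf)
        assert lo[0] == 1.0 and lo[1:].sum() == 0.0
        assert hi[-1] == 1.0 and hi[:-1].sum() == 0.0


class TestPatternLoglikelihood:
    def test_single_item_pattern(self, toy3_params):
        pat = [None, 2, None]
        ll = g.pattern_loglikelihood(toy3_params, pat, 0.5)
        expected = np.log(g.category_probabilities(toy3_params, 1, 0.5)[2])
        assert ll == pytest.approx(expected)

    def test_missing_item_additivity(self, gad7_params):
        full = [1, 0, 2, 3, 1, 0, 2]
        dropped = [1, 0, None, 3, 1, 0, 2]
        theta = 0.3
        term = np.log(g.category_probabilities(gad7_params, 2, theta)[2])
        assert g.pattern_loglikelihood(
            gad7_params, dropped, theta
        ) == pytest.approx(g.pattern_loglikelihood(gad7_params, full, theta) - term)

    def test_two_item_hand_computation(self):
        # independent hand evaluation of the logistic differences
        params = g.GRMParameters(
            discrimination=[2.0, 1.0], thresholds=[[-1.0, 1.0], [0.0, 2.0]]
        )
        theta = 0.5

        def sig(x):
            return 1 / (1 + np.exp(-x))

        # item 0 score 1: P(X>=1) - P(X>=2) at z = 2*0.5
        p0 = sig(1.0 + 1.0) - sig(1.0 - 1.0)
        # item 1 score 2: P(X>=2) at z = 0.5
        p1 = sig(0.5 - 2.0)
        assert g.pattern_loglikelihood(params, [1, 2], theta) == pytest.approx(
            np.log(p0) + np.log(p1)
        )

    def test_all_missing_is_flat(self, gad7_params):
        assert g.pattern_loglikelihood(gad7_params, [None] * 7, 1.7) == 0.0


class TestInformation:
    def test_matches_finite_differences(self, gad7_params):
        # I(theta) = sum_k P_k * (-d^2/dtheta^2 log P_k), via central differences
        grid = np.linspace(-4, 4, 81)
        h = 1e-4
        for j in range(gad7_params.n_items):
            info = g.item_information(gad7_params, j, grid).values
            logp = lambda t: np.log(g.category_probabilities(gad7_params, j, t))
            d2 = (logp(grid + h) - 2 * logp(grid) + logp(grid - h)) / h**2
            p = g.category_probabilities(gad7_params, j, grid)
            expected = np.sum(p * (-d2), axis=-1)
            assert np.allclose(info, expected, atol=1e-5)

    def test_vanishing_discrimination(self):
        params = g.GRMParameters(
            discrimination=[1e-6], thresholds=[[-1.0, 0.0, 1.0]]
        )
        info = g.item_information(params, 0, np.linspace(-4, 4, 41))
        assert np.all(info.values < 1e-10)

    def test_high_discrimination_item_dominates_at_peak(self, gad7_params):
        # item 2 (lambda=3.55) carries more information than item 5 (1.69)
        grid = np.linspace(-4, 4, 161)
        i2 = g.item_information(gad7_params, 1, grid).values
        i5 = g.item_information(gad7_params, 4, grid).values
        assert i2.max() > i5.max()

    def test_test_information_additivity(self, gad7_params):
        grid = np.linspace(-3, 3, 61)
        single = g.test_information(gad7_params, [3], grid)
        assert np.allclose(
            single.values, g.item_information(gad7_params, 3, grid).values
        )
        total = g.test_information(gad7_params, None, grid).values
        parts = sum(
            g.item_information(gad7_params, j, grid).values for j in range(7)
        )
        assert np.allclose(total, parts)

    def test_subset_information_bounded_by_superset(self, gad7_params, rng):
        grid = np.linspace(-4, 4, 81)
        for _ in range(10):
            size = rng.integers(1, 7)
            subset = list(rng.choice(7, size=size, replace=False))
            extra = int(rng.choice([j for j in range(7) if j not in subset]))
            small = g.test_information(gad7_params, subset, grid).values
            large = g.test_information(gad7_params, subset + [extra], grid).values
            assert np.all(large >= small - 1e-12)


class TestBestPredictor:
    def test_worked_examples(self, gad7_params):
        eap1, _ = g.best_predictor(gad7_params, (1, 0, 0, 0, 3, 2, 2))
        eap2, _ = g.best_predictor(gad7_params, (1, 0, 1, 0, 1, 2, 2))
        eap3, _ = g.best_predictor(gad7_params, (1, 1, 1, 3, 3, 3, 3))
        assert round(eap1, 2) == 0.16
        assert round(eap2, 2) == 0.36
        assert round(eap3, 1) == 1.3

    def test_fine_grid_oracle_exhaustive_toy(self, toy3_params):
        fine = np.linspace(-6, 6, 4001)
        for pattern in np.ndindex(4, 4, 4):
            eap, sd = g.best_predictor(toy3_params, pattern)
            eap_f, sd_f = g.best_predictor(toy3_params, pattern, fine)
            assert abs(eap - eap_f) < 1e-4
            assert abs(sd - sd_f) < 1e-4

    def test_fine_grid_oracle_random_patterns(self, gad7_params, rng):
        fine = np.linspace(-6, 6, 4001)
        for _ in range(200):
            pattern = rng.integers(0, 4, size=7)
            eap, _ = g.best_predictor(gad7_params, pattern)
            eap_f, _ = g.best_predictor(gad7_params, pattern, fine)
            assert abs(eap - eap_f) < 1e-4

    def test_monotone_in_each_item(self, gad7_params, rng):
        # raising any single item score cannot lower the EAP (MLR property)
        for _ in range(25):
            pattern = rng.integers(0, 4, size=7)
            j = int(rng.integers(7))
            if pattern[j] == 3:
                pattern[j] = 2
            bumped = pattern.copy()
            bumped[j] += 1
            lo, _ = g.best_predictor(gad7_params, pattern)
            hi, _ = g.best_predictor(gad7_params, bumped)
            assert hi >= lo - 1e-10

    def test_all_missing_returns_prior(self, gad7_params):
        assert g.best_predictor(gad7_params, [None] * 7) == (0.0, 1.0)

    def test_posterior_integrates_prior(self, gad7_params):
        # marginal category frequencies implied by the model match the
        # prior-weighted category response functions (quadrature identity)
        grid = DEFAULT_GRID
        w = norm.pdf(grid)
        for j in range(7):
            p = g.category_probabilities(gad7_params, j, grid)
            marg = np.trapezoid(p * w[:, None], grid, axis=0)
            assert marg.sum() == pytest.approx(1.0, abs=1e-6)


class TestSumScore:
    @pytest.mark.parametrize(
        "pattern, score, band",
        [
            ((0,) * 7, 0, "minimal"),
            ((1, 0, 0, 0, 3, 2, 2), 8, "mild"),
            ((1, 0, 1, 0, 1, 2, 2), 7, "mild"),
            ((2, 2, 1, 2, 1, 2, 1), 11, "moderate"),
            ((1, 1, 1, 3, 3, 3, 3), 15, "severe"),
            ((3,) * 7, 21, "severe"),
        ],
    )
    def test_bands(self, pattern, score, band):
        assert g.sum_score(pattern) == (score, band)

    def test_incomplete_flagged(self):
        score, band = g.sum_score((1, None, 1, 0, 0, 0, 0))
        assert score == 2
        assert "incomplete" in band


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    theta=st.floats(-5, 5),
    lam=st.floats(0.1, 6),
    base=st.floats(-3, 1),
    gaps=st.tuples(st.floats(0.1, 2), st.floats(0.1, 2)),
)
def test_probability_simplex_property(theta, lam, base, gaps):
    """Any valid single-item GRM yields a probability vector at any trait."""
    tau = np.array([base, base + gaps[0], base + gaps[0] + gaps[1]])
    params = g.GRMParameters(discrimination=[lam], thresholds=[tau])
    p = g.category_probabilities(params, 0, theta)
    assert np.all(p >= -1e-12)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)
    info = g.item_information(params, 0, np.array([theta]))
    assert info.values[0] >= 0
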