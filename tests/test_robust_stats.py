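"""Spearman, exact/approximate rank-sum tests, and Wilcoxon-score rank regression."""

import itertools

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from aaflux.robust_stats import (
    rank_regression,
    spearman,
    wilcoxon_dispersion,
    wilcoxon_ranksum_one_sided,
)


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3), (10, 20, 30), 1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),
            ((1, 2, 3), (30, 20, 10), -1.0),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert spearman(x, y).r == pytest.approx(expected, abs=1e-12)

    def test_nan_pairs_dropped(self):
        res = spearman([1, 2, 3, np.nan], [1, 2, 3, 4])
        assert res.n == 3 and res.r == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert not res.ok and np.isnan(res.r)

    @given(
        st.lists(st.floats(-100, 100), min_size=5, max_size=30, unique=True),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transforms(self, xs, transform):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        y = rng.normal(size=len(xs))
        f = {"exp": np.exp, "cube": lambda v: np.asarray(v) ** 3, "affine": lambda v: 3 * np.asarray(v) + 1}[transform]
        x = np.array(xs) / 50.0
        fx = f(x)
        assume(len(np.unique(fx)) == len(x))  # transform must stay injective in floats
        assert spearman(fx, y).r == pytest.approx(spearman(x, y).r, abs=1e-9)


class TestRankSum:
    def test_enumerated_small_sample(self):
        res = wilcoxon_ranksum_one_sided([1, 2], [3, 4], "x_less")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0 / 6.0, abs=1e-12)

    def test_identical_samples_not_significant(self):
        x = list(range(5))
        for alt in ("x_less", "x_greater"):
            assert wilcoxon_ranksum_one_sided(x, x, alt).p_value >= 0.5

    def test_exact_matches_independent_implementation(self):
        """Cross-check enumeration against scipy's exact Mann-Whitney on tie-free data."""
        rng = np.random.default_rng(4)
        for n_x, n_y in [(2, 3), (4, 4), (5, 6), (3, 8)]:
            x = rng.normal(size=n_x)
            y = rng.normal(size=n_y) + 0.5
            ours = wilcoxon_ranksum_one_sided(x, y, "x_less").p_value
            ref = stats.mannwhitneyu(x, y, alternative="less", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_exact_handles_ties(self):
        # all values tied: every assignment gives the same rank sum -> p = 1
        res = wilcoxon_ranksum_one_sided([1, 1], [1, 1], "x_less")
        assert res.p_value == 1.0

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=6)
        y = rng.normal(size=6) + 1.0
        exact = wilcoxon_ranksum_one_sided(x, y, "x_less").p_value
        from aaflux.robust_stats import _normal_ranksum_p

        approx = _normal_ranksum_p(x, y, "x_less")
        assert approx == pytest.approx(exact, abs=0.01)

    def test_antisymmetry_of_alternatives(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=25) + 0.3
        p1 = wilcoxon_ranksum_one_sided(x, y, "x_less").p_value
        p2 = wilcoxon_ranksum_one_sided(y, x, "x_greater").p_value
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestRankRegression:
    def test_noise_free_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        fit = rank_regression(x.reshape(-1, 1), 1.0 + 2.0 * x, names=["x"])
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-6)
        assert fit.intercept == pytest.approx(1.0, abs=1e-6)
        assert fit.total_r == pytest.approx(1.0, abs=1e-6)

    def test_laplace_noise_recovery(self):
        slopes = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=500)
            y = 1.0 + 2.0 * x + rng.laplace(scale=1.0, size=500)
            slopes.append(rank_regression(x.reshape(-1, 1), y, names=["x"]).coefficients["x"])
        assert np.median(slopes) == pytest.approx(2.0, abs=0.1)

    def test_outlier_resistance_beats_least_squares(self):
        """Rank slope closer to truth than OLS in >= 90% of contaminated replicates."""
        wins = 0
        n, n_rep = 60, 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=n)
            y = 1.0 + 2.0 * x + rng.normal(size=n)
            out = rng.choice(n, size=n // 10, replace=False)
            y[out] += 50.0
            rank_slope = rank_regression(x.reshape(-1, 1), y).coefficients["x0"]
            ols_slope = np.polyfit(x, y, 1)[0]
            wins += abs(rank_slope - 2.0) < abs(ols_slope - 2.0)
        assert wins >= 0.9 * n_rep

    def test_fit_dispersion_below_grid_perturbations(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 2))
        y = X @ np.array([1.0, -1.0]) + rng.laplace(size=200)
        fit = rank_regression(X, y)
        beta = np.array([fit.coefficients["x0"], fit.coefficients["x1"]])
        d_fit = wilcoxon_dispersion(y - X @ beta)
        assert d_fit == pytest.approx(fit.dispersion_full)
        for eps in (1e-3, 1e-2, 0.1, 1.0):
            for direction in itertools.product((-1, 0, 1), repeat=2):
                if direction == (0, 0):
                    continue
                b = beta + eps * np.array(direction)
                assert wilcoxon_dispersion(y - X @ b) >= d_fit - 1e-9

    def test_dispersion_full_never_exceeds_null(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 3))
        y = rng.normal(size=100)  # pure noise
        fit = rank_regression(X, y)
        assert fit.dispersion_full <= fit.dispersion_null
        assert 0.0 <= fit.total_r <= 1.0

    def test_total_r_near_zero_for_independent_noise(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        fit = rank_regression(x.reshape(-1, 1), y)
        assert fit.total_r < 0.1

    def test_slope_sign_matches_spearman_on_monotone_data(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        for slope in (1.5, -1.5):
            y = slope * x + 0.2 * rng.normal(size=100)
            fit = rank_regression(x.reshape(-1, 1), y)
            assert np.sign(fit.coefficients["x0"]) == np.sign(spearman(x, y).r)

    def test_significant_covariate_has_small_p(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(300, 2))
        y = X @ np.array([1.0, 0.0]) + rng.normal(size=300)
        fit = rank_regression(X, y)
        assert fit.p_values["x0"] < 1e-6
        assert fit.p_values["x1"] > 0.01

    def test_rank_deficient_matrix_rejected(self):
        x = np.arange(20.0)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank-deficient"):
            rank_regression(X, x)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            rank_regression(np.ones((2, 1)) * [[1.0], [2.0]], np.array([1.0, 2.0]))
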