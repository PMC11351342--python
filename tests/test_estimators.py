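"""Causal-effect estimators against closed forms and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mrmediate import (
    EstimatorError,
    ivw,
    mode_estimator,
    mr_egger,
    run_all_methods,
    wald_ratio,
    weighted_median,
)
from mrmediate.estimators import estimates_to_table
from conftest import make_harmonized


def wls_oracle(x, y, w, intercept):
    """Brute-force weighted least squares via explicit matrix algebra.

    Independent of the estimator code path: builds the design matrix,
    inverts X'WX, and computes fixed SEs from the unscaled covariance.
    """
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    W = np.diag(w)
    xtwx_inv = np.linalg.inv(X.T @ W @ X)
    coef = xtwx_inv @ X.T @ W @ y
    se = np.sqrt(np.diag(xtwx_inv))
    resid = y - X @ coef
    rss = float(resid @ W @ resid)
    return coef, se, rss


class TestWaldRatio:
    def test_ratio_arithmetic(self):
        h = make_harmonized([0.5], [0.05], [0.25], [0.10])
        e = wald_ratio(h)
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.2)

    def test_zero_outcome_beta(self):
        e = wald_ratio(make_harmonized([0.5], [0.05], [0.0], [0.1]))
        assert e.beta == 0.0
        assert e.pval == pytest.approx(1.0)

    def test_zero_exposure_beta_fatal(self):
        with pytest.raises(EstimatorError):
            wald_ratio(make_harmonized([0.0], [0.05], [0.1], [0.1]))

    def test_second_order_se_matches_monte_carlo(self, rng):
        """Delta-method SE vs the simulated SD of the ratio at strong bx."""
        bx, sx, by, sy = 0.5, 0.05, 0.25, 0.10  # |bx/sx| = 10
        e = wald_ratio(make_harmonized([bx], [sx], [by], [sy]), second_order=True)
        n = 10**6
        draws = rng.normal(by, sy, n) / rng.normal(bx, sx, n)
        assert e.se == pytest.approx(np.std(draws), rel=0.05)


class TestIVW:
    def test_symmetric_pair(self):
        h = make_harmonized([1.0, 1.0], [0.01], [0.4, 0.6], [1.0, 1.0])
        e = ivw(h)
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(1 / np.sqrt(2))

    def test_single_record_delegates_to_wald(self):
        h = make_harmonized([0.5], [0.05], [0.25], [0.10])
        a, b = ivw(h), wald_ratio(h)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(10):
            k = int(rng.integers(3, 60))
            bx = rng.normal(0.1, 0.05, k)
            by = rng.normal(0.05, 0.1, k)
            sy = rng.uniform(0.02, 0.3, k)
            h = make_harmonized(bx, np.full(k, 0.01), by, sy)
            e = ivw(h, "fixed")
            coef, se, _ = wls_oracle(bx, by, 1 / sy**2, intercept=False)
            assert e.beta == pytest.approx(coef[0], abs=1e-10)
            assert e.se == pytest.approx(se[0], abs=1e-10)

    def test_equal_weights_unit_bx_is_mean(self, rng):
        by = rng.normal(size=8)
        h = make_harmonized(np.ones(8), np.full(8, 0.01), by, np.ones(8))
        assert ivw(h).beta == pytest.approx(by.mean())

    def test_random_effects_inflates_only_when_q_large(self):
        homog = make_harmonized([1, 1], [0.01], [0.5, 0.5], [1, 1])
        assert ivw(homog, "random").se == pytest.approx(ivw(homog, "fixed").se)
        heterog = make_harmonized([1, 1], [0.01], [-3.0, 3.0], [0.1, 0.1])
        assert ivw(heterog, "random").se > ivw(heterog, "fixed").se


class TestEgger:
    def test_exact_collinear_fit(self):
        h = make_harmonized([1, 2, 3], [0.01], [0.6, 1.1, 1.6], [1, 1, 1])
        res = mr_egger(h)
        assert res.slope.beta == pytest.approx(0.5)
        assert res.intercept == pytest.approx(0.1)

    def test_two_records_fatal(self):
        with pytest.raises(EstimatorError, match="insufficient"):
            mr_egger(make_harmonized([1, 2], [0.01], [0.5, 1.0], [1, 1]))

    def test_matches_wls_with_intercept_oracle(self, rng):
        for _ in range(10):
            k = int(rng.integers(3, 60))
            bx = rng.uniform(0.05, 0.3, k)
            by = rng.normal(0.1 * bx, 0.05)
            sy = rng.uniform(0.02, 0.3, k)
            h = make_harmonized(bx, np.full(k, 0.01), by, sy)
            res = mr_egger(h)
            coef, se, rss = wls_oracle(bx, by, 1 / sy**2, intercept=True)
            scale = max(1.0, rss / (k - 2))
            assert res.slope.beta == pytest.approx(coef[1], abs=1e-10)
            assert res.intercept == pytest.approx(coef[0], abs=1e-10)
            assert res.slope.se == pytest.approx(se[1] * np.sqrt(scale), abs=1e-10)
            assert res.intercept_se == pytest.approx(se[0] * np.sqrt(scale), abs=1e-10)

    def test_recovers_directional_pleiotropy_intercept(self, rng):
        """Ratio estimates all shifted by +0.2/bx -> intercept near 0.2."""
        intercepts = []
        for _ in range(50):
            k = 30
            bx = rng.uniform(0.1, 0.5, k)
            sy = np.full(k, 0.05)
            by = 0.3 * bx + 0.2 + rng.normal(0, sy)
            h = make_harmonized(bx, np.full(k, 0.001), by, sy)
            intercepts.append(mr_egger(h).intercept)
        assert np.mean(intercepts) == pytest.approx(0.2, abs=0.02)


class TestWeightedMedian:
    def test_equal_weights_middle_order_statistic(self):
        h = make_harmonized([1, 1, 1], [0.01], [0.2, 0.5, 0.8], [1, 1, 1])
        assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(0.5)

    def test_dominant_weight_pulls_estimate(self):
        # weight ~ 1/se^2: tiny se on the 0.8-ratio SNP dominates
        h = make_harmonized([1, 1, 1], [0.001], [0.2, 0.5, 0.8], [1.0, 1.0, 0.01])
        assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(0.8, abs=0.01)

    def test_equals_plain_median_equal_weights_odd_n(self, rng):
        by = rng.normal(0.3, 0.2, 9)
        h = make_harmonized(np.ones(9), np.full(9, 0.001), by, np.ones(9))
        assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(
            np.median(by), abs=1e-9
        )

    def test_bootstrap_se_converges(self):
        h = make_harmonized(
            np.linspace(0.2, 0.6, 10), np.full(10, 0.02),
            np.linspace(0.1, 0.35, 10), np.full(10, 0.05),
        )
        se_small = weighted_median(h, n_boot=1000, seed=5).se
        se_big = weighted_median(h, n_boot=100_000, seed=6).se
        assert se_small == pytest.approx(se_big, rel=0.15)


class TestMode:
    def test_point_mass(self):
        h = make_harmonized([1, 1, 1], [0.01], [0.3, 0.3, 0.3], [1, 1, 1])
        assert mode_estimator(h, n_boot=50, seed=1).beta == pytest.approx(0.3)

    def test_mixture_mode_near_majority_cluster(self, rng):
        ratios = np.r_[rng.normal(0.5, 0.02, 7), rng.normal(2.0, 0.02, 3)]
        h = make_harmonized(np.ones(10), np.full(10, 0.001), ratios, np.full(10, 0.05))
        est = mode_estimator(h, "simple", n_boot=50, seed=1)
        # independent fine-grid density oracle over the same kernel rule
        grid = np.linspace(-1, 3, 20001)
        n = len(ratios)
        bw = 0.9 * min(np.std(ratios, ddof=1),
                       stats.median_abs_deviation(ratios, scale="normal")) / n**0.2
        dens = np.exp(-0.5 * ((grid[:, None] - ratios) / bw) ** 2).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        assert est.beta == pytest.approx(oracle, abs=0.01)
        assert abs(est.beta - 0.5) < 0.2

    def test_weighted_variant_follows_weight(self):
        ratios = np.array([0.5, 0.52, 0.48, 2.0, 2.01, 1.99])
        sy = np.array([1.0, 1.0, 1.0, 0.01, 0.01, 0.01])  # all weight on the 2.0 cluster
        h = make_harmonized(np.ones(6), np.full(6, 0.001), ratios, sy)
        est = mode_estimator(h, "weighted", n_boot=50, seed=1)
        assert est.beta == pytest.approx(2.0, abs=0.05)


class TestRunAll:
    def test_single_record_wald_only(self):
        h = make_harmonized([0.5], [0.05], [0.25], [0.1])
        out = run_all_methods(h)
        assert [e.method for e in out] == ["Wald ratio"]

    def test_five_method_table_shape(self, rng):
        k = 20
        h = make_harmonized(
            rng.uniform(0.1, 0.3, k), np.full(k, 0.01),
            rng.normal(0, 0.05, k), np.full(k, 0.05),
        )
        table = estimates_to_table(run_all_methods(h, n_boot=50), binary_outcome=True)
        assert list(table["method"]) == [
            "MR Egger", "Weighted median", "IVW", "Simple mode", "Weighted mode"
        ]
        assert {"nsnp", "pval", "or", "or_ci_low", "or_ci_high"} <= set(table.columns)
        np.testing.assert_allclose(table["or"], np.exp(table["beta"]))

    def test_null_input_gives_or_near_one(self):
        h = make_harmonized([0.2, 0.25, 0.3, 0.35, 0.4], [0.01], [0.0] * 5, [0.05])
        table = estimates_to_table(run_all_methods(h, n_boot=50), binary_outcome=True)
        np.testing.assert_allclose(table["or"], 1.0, atol=0.05)

    @settings(max_examples=20, deadline=None)
    @given(c=st.floats(min_value=0.1, max_value=10).flatmap(
        lambda v: st.sampled_from([v, -v])))
    def test_scale_equivariance(self, c):
        """Rescaling exposure betas and SEs by c divides every estimate by c."""
        rng = np.random.default_rng(11)
        k = 12
        bx = rng.uniform(0.1, 0.4, k)
        h1 = make_harmonized(bx, np.full(k, 0.01), 0.3 * bx + rng.normal(0, 0.02, k),
                             np.full(k, 0.05))
        h2 = h1.copy()
        h2["beta_exp"] *= c
        h2["se_exp"] *= abs(c)
        for est1, est2 in zip(run_all_methods(h1, n_boot=40, seed=3),
                              run_all_methods(h2, n_boot=40, seed=3)):
            assert est2.beta * c == pytest.approx(est1.beta, rel=1e-6, abs=1e-9)
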