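"""Synthetic cohort generator, per-SNP GWAS scans and 2SLS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrmediate import (
    ScenarioError,
    build_scenario,
    simulate_cohort,
    summary_stats_from_cohort,
    two_stage_least_squares,
    wald_ratio,
    harmonize_pair,
)


def _meta(n_snps):
    return pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(n_snps)],
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1) * 10**6,
            "effect_allele": "A",
            "other_allele": "G",
        }
    ).set_index("snp", drop=False)


class TestSimulateCohort:
    def test_same_seed_bit_identical(self):
        cfg = build_scenario("mediated", n_per_cohort=500, n_snps=10, n_own_snps=5, seed=9)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.exposure, b.exposure)
        np.testing.assert_array_equal(a.mediators, b.mediators)
        np.testing.assert_array_equal(a.outcome, b.outcome)

    def test_null_scenario_no_exposure_outcome_correlation(self):
        cfg = build_scenario("null", n_per_cohort=5000, seed=3)
        c = simulate_cohort(cfg)
        n = len(c.exposure)
        r = np.corrcoef(c.exposure, c.outcome)[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_heritability_targeting(self):
        """Realized instrument R^2 tracks the requested exposure_h2."""
        r2s = []
        for seed in range(100):
            cfg = build_scenario(
                "null", exposure_h2=0.05, n_per_cohort=20_000, n_snps=50,
                n_own_snps=0, own_h2=0.0, seed=seed,
            )
            c = simulate_cohort(cfg)
            idx = c.roles["exposure"]
            g = c.genotypes[idx].astype(float)
            x = c.exposure[idx]
            coef, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(x)), g]), x, rcond=None
            )
            fitted = np.column_stack([np.ones(len(x)), g]) @ coef
            r2 = 1 - np.var(x - fitted) / np.var(x)
            # adjusted R^2 removes the K/n overfitting inflation of the fit
            k = g.shape[1]
            r2s.append(1 - (1 - r2) * (len(x) - 1) / (len(x) - k - 1))
        r2s = np.asarray(r2s)
        assert np.all((r2s > 0.04) & (r2s < 0.06))

    def test_outcome_prevalence_matches_target(self):
        cfg = build_scenario("mediated", n_per_cohort=20_000, outcome_prevalence=0.1, seed=5)
        c = simulate_cohort(cfg)
        assert np.mean(c.outcome) == pytest.approx(0.1, abs=0.01)

    def test_infeasible_variance_fatal(self):
        cfg = build_scenario("mediated", theta1=0.9, own_h2=0.3, seed=1)
        with pytest.raises(ScenarioError, match="infeasible"):
            simulate_cohort(cfg)

    def test_ld_blocks_hit_target_r2(self):
        cfg = build_scenario(
            "null", n_per_cohort=8000, n_snps=12, n_own_snps=0, own_h2=0.0,
            ld_blocks=(4, 0.3), seed=11,
        )
        c = simulate_cohort(cfg)
        g = c.genotypes[c.roles["exposure"]].astype(float)
        within = []
        for b in range(3):
            cols = slice(4 * b, 4 * b + 4)
            r = np.corrcoef(g[:, cols], rowvar=False)
            within.extend((r[np.triu_indices(4, 1)] ** 2).tolist())
        assert np.mean(within) == pytest.approx(0.3, abs=0.05)

    def test_disjoint_roles_by_default(self):
        cfg = build_scenario("null", n_per_cohort=100, seed=2)
        c = simulate_cohort(cfg)
        spans = [set(range(s.start, s.stop)) for s in c.roles.values()]
        assert not (spans[0] & spans[1]) and not (spans[1] & spans[2])


class TestSummaryStats:
    def test_constructed_signal_recovered_exactly(self, rng):
        n, j = 400, 6
        g = rng.binomial(2, 0.3, size=(n, j))
        y = 2.0 * g[:, 2].astype(float)
        t = summary_stats_from_cohort(g, y, "continuous", _meta(j))
        assert t.records.loc[2, "beta"] == pytest.approx(2.0, abs=1e-12)

    def test_ols_betas_match_closed_form(self, rng):
        n, j = 500, 10
        g = rng.binomial(2, 0.4, size=(n, j)).astype(float)
        y = rng.normal(size=n)
        t = summary_stats_from_cohort(g, y, "continuous", _meta(j))
        for k in range(j):
            expected = np.cov(g[:, k], y)[0, 1] / np.var(g[:, k], ddof=1)
            assert t.records.loc[k, "beta"] == pytest.approx(expected, abs=1e-10)

    def test_null_z_squared_is_chi2(self, rng):
        n, j = 600, 2000
        g = rng.binomial(2, 0.3, size=(n, j))
        y = rng.normal(size=n)
        t = summary_stats_from_cohort(g, y, "continuous", _meta(j))
        z2 = (t.records["beta"] / t.records["se"]) ** 2
        ks = stats.kstest(z2, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_logistic_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n, j = 800, 4
        g = rng.binomial(2, 0.3, size=(n, j))
        logits = -1.0 + 0.4 * g[:, 0]
        y = rng.random(n) < 1 / (1 + np.exp(-logits))
        t = summary_stats_from_cohort(g, y.astype(float), "binary", _meta(j))
        for k in range(j):
            fit = sm.Logit(y, sm.add_constant(g[:, k].astype(float))).fit(disp=0)
            assert t.records.loc[k, "beta"] == pytest.approx(fit.params[1], abs=1e-6)
            assert t.records.loc[k, "se"] == pytest.approx(fit.bse[1], rel=1e-4)

    def test_monomorphic_snp_flagged_not_fatal(self, rng):
        n, j = 200, 3
        g = rng.binomial(2, 0.3, size=(n, j))
        g[:, 1] = 2  # monomorphic
        y = rng.normal(size=n)
        t = summary_stats_from_cohort(g, y, "continuous", _meta(j))
        assert t.records.loc[1, "eaf"] == 1.0
        assert t.records.loc[1, "beta"] == 0.0

    def test_length_mismatch_fatal(self, rng):
        with pytest.raises(ValueError, match="length"):
            summary_stats_from_cohort(
                rng.binomial(2, 0.3, size=(10, 2)), np.zeros(9), "continuous", _meta(2)
            )


class TestTSLS:
    def test_single_instrument_equals_wald_ratio(self, rng):
        n = 3000
        g = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        x = 0.5 * g[:, 0] + rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n)
        res = two_stage_least_squares(g, x, y)
        exp_t = summary_stats_from_cohort(g, x, "continuous", _meta(1), trait_id="x")
        out_t = summary_stats_from_cohort(g, y, "continuous", _meta(1), trait_id="y")
        h = harmonize_pair(exp_t, out_t)
        assert res.beta == pytest.approx(wald_ratio(h).beta, abs=1e-6)

    def test_exposure_on_itself_gives_unit_beta(self, rng):
        n = 500
        g = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        x = 0.4 * g.sum(axis=1) + rng.normal(size=n)
        res = two_stage_least_squares(g, x, x)
        assert res.beta == pytest.approx(1.0, abs=1e-10)

    def test_null_pvalues_uniform(self, rng):
        pvals = []
        for _ in range(500):
            n = 300
            g = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
            x = 0.5 * g.sum(axis=1) + rng.normal(size=n)
            y = rng.normal(size=n)  # independent of exposure
            pvals.append(two_stage_least_squares(g, x, y).pval)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_rank_deficient_fatal(self, rng):
        n = 100
        g = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        g2 = np.column_stack([g, g])  # duplicated instrument
        x = g[:, 0] + rng.normal(size=n)
        with pytest.raises(ScenarioError, match="rank"):
            two_stage_least_squares(g2, x, x)

    def test_stage1_r2_reported(self, rng):
        n = 2000
        g = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        x = 0.3 * g.sum(axis=1) + rng.normal(size=n)
        res = two_stage_least_squares(g, x, 0.5 * x + rng.normal(size=n))
        assert 0 < res.stage1_r2 < 1


class TestScenarios:
    def test_null_preset_all_zero(self):
        cfg = build_scenario("null")
        assert cfg.theta1 == cfg.theta2 == cfg.delta_direct == 0.0

    def test_mediated_truth_indirect(self):
        cfg = build_scenario("mediated", n_per_cohort=300, n_snps=5, n_own_snps=3, seed=1)
        c = simulate_cohort(cfg)
        assert c.truth.indirect[0] == pytest.approx(0.2)

    def test_unknown_name_lists_valid(self):
        with pytest.raises(ScenarioError, match="mediated"):
            build_scenario("not_a_scenario")

    def test_presets_run_end_to_end_small(self):
        """Every preset simulates and produces GWAS tables without error."""
        for name in ("null", "mediated", "direct_only", "pleiotropic",
                     "heterogeneous", "reverse"):
            cfg = build_scenario(name, n_per_cohort=400, n_snps=8, n_own_snps=6, seed=4)
            c = simulate_cohort(cfg)
            assert c.gwas("exposure").n_snps == 14
            assert c.gwas("outcome").trait_type == "binary"
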