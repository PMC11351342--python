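"""Benchmark routines: calibration, recovery and robustness of the suite.

Each function simulates seeded synthetic studies under a named scenario
preset, runs the estimator or screening machinery, and reports summary
metrics (type-I error rates, mean recovered effects, ordering
frequencies).  They power both the acceptance checks and any user who
wants to reproduce the operating characteristics of the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import sensitivity
from .estimators import ivw, mr_egger, weighted_median, wald_ratio
from .gwas_io import SummaryStatTable, harmonize_pair
from .mediation import sobel_mediation
from .pipeline import RunConfig, run_two_step
from .synthetic import (
    Cohort,
    build_scenario,
    screening_fixture,
    simulate_cohort,
    two_stage_least_squares,
)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return np.array([int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)])


def _subset(table: SummaryStatTable, snps: list[str]) -> SummaryStatTable:
    recs = table.records[table.records["snp"].isin(snps)].reset_index(drop=True)
    return SummaryStatTable(table.trait_id, table.trait_type, recs)


def _harmonized_truth(cohort: Cohort, exp_trait: str, out_trait: str) -> pd.DataFrame:
    """Harmonized set over the scenario's true instruments."""
    snps = cohort.truth.instrument_snps
    exp = _subset(cohort.gwas(exp_trait, trait_id="exp"), snps)
    out = cohort.gwas(out_trait, trait_id="out")
    return harmonize_pair(exp, out)


# --- 1. estimator vs brute-force WLS oracle -----------------------------


def estimator_oracle_gap(n_instances: int = 100, seed: int = 0) -> dict:
    """Largest |IVW/Egger - brute-force WLS| over random instances.

    The oracle builds the (weighted) design matrix explicitly and solves
    the normal equations with dense linear algebra, independently of the
    closed-form accumulation the estimators use.
    """
    rng = np.random.default_rng(seed)
    gaps = dict(ivw_beta=0.0, ivw_se=0.0, egger_beta=0.0, egger_se=0.0)
    for _ in range(n_instances):
        k = int(rng.integers(3, 201))
        bx = rng.normal(0.1, 0.08, k)
        bx[bx == 0] = 0.05
        by = rng.normal(0.05 * bx, 0.1)
        sy = rng.uniform(0.01, 0.5, k)
        h = pd.DataFrame(
            {
                "snp": [f"s{i}" for i in range(k)],
                "beta_exp": bx, "se_exp": 0.01, "pval_exp": 1e-9, "n_exp": 1e4,
                "beta_out": by, "se_out": sy, "pval_out": 0.5, "n_out": 1e4,
                "eaf": 0.3, "flipped": False, "palindromic": False,
            }
        )
        w = 1.0 / sy**2
        sw = np.sqrt(w)
        # IVW oracle: WLS through the origin via lstsq
        coef, *_ = np.linalg.lstsq((sw * bx)[:, None], sw * by, rcond=None)
        se0 = float(np.sum(w * bx**2)) ** -0.5
        e = ivw(h, "fixed")
        gaps["ivw_beta"] = max(gaps["ivw_beta"], abs(e.beta - coef[0]))
        gaps["ivw_se"] = max(gaps["ivw_se"], abs(e.se - se0))
        # Egger oracle: WLS with intercept on orientation-corrected data
        sgn = np.where(bx < 0, -1.0, 1.0)
        X = np.column_stack([np.ones(k), bx * sgn])
        coef2, *_ = np.linalg.lstsq(sw[:, None] * X, sw * (by * sgn), rcond=None)
        cov_u = np.linalg.inv(X.T @ np.diag(w) @ X)
        resid = by * sgn - X @ coef2
        scale = max(1.0, float(resid @ (w * resid)) / (k - 2))
        res = mr_egger(h)
        gaps["egger_beta"] = max(gaps["egger_beta"], abs(res.slope.beta - coef2[1]))
        gaps["egger_se"] = max(
            gaps["egger_se"], abs(res.slope.se - np.sqrt(cov_u[1, 1] * scale))
        )
    return gaps


# --- 2. closed-form worked examples -------------------------------------


def closed_form_examples() -> dict:
    """The hand-computable quantities of the worked examples."""
    from .instruments import compute_f_statistics, select_genomewide

    f_stat = 0.02 * (5001 - 1 - 1) / (1 * (1 - 0.02))
    h = pd.DataFrame(
        {
            "snp": ["rs1"], "beta_exp": [0.5], "se_exp": [0.05], "pval_exp": [1e-9],
            "n_exp": [1e4], "beta_out": [0.25], "se_out": [0.10], "pval_out": [0.01],
            "n_out": [1e4], "eaf": [0.3], "flipped": [False], "palindromic": [False],
        }
    )
    wald = wald_ratio(h)
    h2 = pd.DataFrame(
        {
            "snp": ["a", "b"], "beta_exp": [1.0, 1.0], "se_exp": 0.01,
            "pval_exp": 1e-9, "n_exp": 1e4,
            "beta_out": [0.0, 2.0], "se_out": 1.0, "pval_out": 0.5, "n_out": 1e4,
            "eaf": 0.3, "flipped": False, "palindromic": False,
        }
    )
    q, qdf, qp = sensitivity.cochran_q(h2, beta_ivw=1.0)
    z_steiger = (np.arctanh(0.2) - np.arctanh(0.01)) / np.sqrt(2 / (10_000 - 3))
    sobel = sobel_mediation(0.5, 0.1, 0.4, 0.1)
    return dict(
        f_stat=f_stat,
        wald_beta=wald.beta, wald_se=wald.se,
        q_stat=q, q_pval=qp,
        steiger_z=float(z_steiger),
        sobel_se=sobel.sobel_se, sobel_z=sobel.z_stat,
        sobel_ci_low=sobel.ci_low, sobel_ci_high=sobel.ci_high,
    )


# --- 3. null calibration -------------------------------------------------


def null_calibration(n_reps: int = 1000, seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of IVW, Egger slope, Q and Egger intercept under the null.

    Null preset: no causal effect, no pleiotropy, no heterogeneity;
    n = 20,000 per cohort, 50 instruments; exposure and outcome GWAS from
    disjoint cohorts; the scenario's true instruments are used directly so
    the rejection rates measure the estimators, not selection effects.
    """
    rej = dict(ivw=0, egger=0, q=0, egger_intercept=0)
    for s in _child_seeds(seed, n_reps):
        cfg = build_scenario("null", seed=int(s), n_own_snps=0, own_h2=0.0)
        cohort = simulate_cohort(cfg)
        h = _harmonized_truth(cohort, "exposure", "mediator")
        rej["ivw"] += ivw(h, "fixed").pval < alpha
        egger = mr_egger(h)
        rej["egger"] += egger.slope.pval < alpha
        rej["egger_intercept"] += egger.intercept_pval < alpha
        _, _, qp = sensitivity.cochran_q(h)
        rej["q"] += qp < alpha
    return {k: v / n_reps for k, v in rej.items()}


# --- 4. parameter recovery ----------------------------------------------


def mediated_recovery(n_reps: int = 200, seed: int = 0) -> dict:
    """Mean recovered theta1, theta2 and Sobel indirect effect (truth 0.4/0.5/0.2).

    Step 1 uses the exposure's instruments against the mediator GWAS;
    step 2 the mediator's own instruments against the binary-outcome GWAS
    (log-odds scale); the indirect effect is the per-replicate product of
    coefficients.
    """
    b1s, b2s, indirects = [], [], []
    for s in _child_seeds(seed, n_reps):
        cohort = simulate_cohort(build_scenario("mediated", seed=int(s)))
        h1 = _harmonized_truth(cohort, "exposure", "mediator")
        e1 = ivw(h1, "fixed")
        own = cohort.truth.own_snps[0]
        med = _subset(cohort.gwas("mediator", trait_id="med"), own)
        h2 = harmonize_pair(med, cohort.gwas("outcome", trait_id="out"))
        e2 = ivw(h2, "fixed")
        res = sobel_mediation(e1.beta, e1.se, e2.beta, e2.se)
        b1s.append(e1.beta)
        b2s.append(e2.beta)
        indirects.append(res.indirect)
    return dict(
        mean_b1=float(np.mean(b1s)),
        mean_b2=float(np.mean(b2s)),
        mean_indirect=float(np.mean(indirects)),
        n_reps=n_reps,
    )


# --- 5. robustness ordering ---------------------------------------------


def robustness_ordering(n_reps: int = 200, seed: int = 0) -> dict:
    """Fraction of replicates where the weighted median beats IVW in |bias|.

    Pleiotropic preset: 30% of instruments carry a constant directional
    direct effect on the mediator; truth theta1 = 0.4.
    """
    wins = 0
    theta1 = 0.4
    for s in _child_seeds(seed, n_reps):
        cohort = simulate_cohort(build_scenario("pleiotropic", seed=int(s)))
        h = _harmonized_truth(cohort, "exposure", "mediator")
        bias_ivw = abs(ivw(h, "fixed").beta - theta1)
        bias_wm = abs(weighted_median(h, n_boot=16, seed=int(s)).beta - theta1)
        wins += bias_wm < bias_ivw
    return dict(frac_wm_less_biased=wins / n_reps, n_reps=n_reps)


# --- 6. directionality ---------------------------------------------------


def directionality(n_reps: int = 100, seed: int = 0) -> dict:
    """Steiger verdict frequencies on the reverse and mediated presets."""
    seeds = _child_seeds(seed, 2 * n_reps)
    n_false = 0
    for s in seeds[:n_reps]:
        cohort = simulate_cohort(build_scenario("reverse", seed=int(s)))
        h = _harmonized_truth(cohort, "exposure", "mediator")
        n_false += sensitivity.steiger_direction(h).direction == "false"
    n_true = 0
    for s in seeds[n_reps:]:
        cohort = simulate_cohort(build_scenario("mediated", seed=int(s)))
        h = _harmonized_truth(cohort, "exposure", "mediator")
        n_true += sensitivity.steiger_direction(h).direction == "true"
    return dict(
        frac_false_on_reverse=n_false / n_reps,
        frac_true_on_mediated=n_true / n_reps,
        n_reps=n_reps,
    )


# --- 7. 2SLS / IVW concordance ------------------------------------------


def tsls_ivw_concordance(n_reps: int = 200, seed: int = 0) -> dict:
    """One-cohort agreement of 2SLS and summary-level IVW within 2 SEs."""
    agree = 0
    for s in _child_seeds(seed, n_reps):
        cfg = build_scenario("mediated", n_per_cohort=4000, n_snps=25,
                             n_own_snps=0, own_h2=0.0, seed=int(s))
        cohort = simulate_cohort(cfg)
        idx = cohort.roles["mediator"]
        snps = cohort.truth.instrument_snps
        g = cohort.genotype_matrix(snps, "mediator")
        x = cohort.exposure[idx]
        m = cohort.mediators[idx, 0]
        res = two_stage_least_squares(g, x, m)
        exp_t = _subset(
            cohort.gwas("exposure", role="mediator", trait_id="exp"), snps
        )
        out_t = cohort.gwas("mediator", role="mediator", trait_id="med")
        h = harmonize_pair(exp_t, out_t)
        e = ivw(h, "fixed")
        agree += abs(res.beta - e.beta) <= 2 * max(res.se, e.se)
    return dict(frac_within_2se=agree / n_reps, n_reps=n_reps)


# --- 8. screening-cascade fidelity --------------------------------------


def screening_fidelity(n_boot: int = 200) -> dict:
    """Survivors of the packaged 10-mediator fixture (designed truth: 3)."""
    cohort = screening_fixture()
    exposure = cohort.gwas("exposure", trait_id="exposure")
    outcome = cohort.gwas("outcome", trait_id="outcome")
    mediators = [cohort.gwas(n, trait_id=n) for n in cohort.mediator_names]
    config = RunConfig(n_boot=n_boot, seed=1)
    report = run_two_step(
        exposure, mediators, outcome, config, cohort=cohort, bidirectional=False
    )
    t = report.mediation_table
    survivors = sorted(t.loc[t["final_pass"], "mediator_id"])
    designed = ["region_a:true1", "region_a:true2", "region_b:true3"]
    return dict(
        n_survivors=len(survivors),
        survivors=survivors,
        matches_design=survivors == designed,
        report=report,
    )


# --- 9. determinism & conservation --------------------------------------


def determinism_check(seed: int = 0) -> dict:
    """Fixed-seed rerun equality and per-stage count conservation."""
    import filecmp
    import tempfile
    from pathlib import Path

    cohort = simulate_cohort(
        build_scenario("mediated", n_per_cohort=4000, seed=seed)
    )
    tables = (
        cohort.gwas("exposure", trait_id="exposure"),
        [cohort.gwas("mediator", trait_id="mediator")],
        cohort.gwas("outcome", trait_id="outcome"),
    )
    identical = True
    conserved = True
    with tempfile.TemporaryDirectory() as tmp:
        dirs = []
        for name in ("a", "b"):
            rep = run_two_step(
                tables[0], tables[1], tables[2],
                RunConfig(n_boot=100, seed=seed), cohort=cohort, bidirectional=False,
            )
            try:
                rep.provenance()  # asserts conservation internally
            except AssertionError:
                conserved = False
            out = Path(tmp) / name
            rep.write(out)
            dirs.append(out)
        for f in sorted((dirs[0] / "tables").iterdir()):
            if not filecmp.cmp(f, dirs[1] / "tables" / f.name, shallow=False):
                identical = False
    return dict(byte_identical=identical, counts_conserved=conserved)
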