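"""Heterogeneity, pleiotropy, directionality and influence diagnostics.

Attached to any estimator run:

* Cochran's Q against the fixed-effect IVW fit, chi-square with nsnp-1 df
  under homogeneity;
* the MR-Egger intercept test for directional horizontal pleiotropy;
* leave-one-out IVW estimates with flags for SNPs whose exclusion changes
  the significance verdict;
* the Steiger directionality test: instruments should explain more variance
  in the exposure than in the outcome if causality runs exposure -> outcome;
* plot-ready funnel and scatter coordinate tables (no rendering here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import estimators
from .estimators import EstimatorError, MREstimate


@dataclass
class SteigerResult:
    direction: str          # "true" | "false" | "uncertain"
    pval: float
    r2_exposure: float
    r2_outcome: float
    #: r2 for binary traits is an observed-scale approximation from the
    #: per-SNP t-statistics; flagged so liability-scale values can be
    #: substituted upstream.
    approximation: str = "t-statistic observed-scale r2"


@dataclass
class SensitivityReport:
    """Diagnostics for one MR run (one exposure-outcome pair)."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_pval: float = np.nan
    steiger: SteigerResult | None = None
    loo_estimates: pd.DataFrame | None = field(default=None, repr=False)
    funnel_points: pd.DataFrame | None = field(default=None, repr=False)
    scatter_points: pd.DataFrame | None = field(default=None, repr=False)
    scatter_lines: pd.DataFrame | None = field(default=None, repr=False)

    def summary_row(self) -> dict:
        return dict(
            q_stat=self.q_stat, q_df=self.q_df, p_het=self.q_pval,
            egger_intercept=self.egger_intercept,
            p_ple=self.egger_intercept_pval,
            steiger_direction=self.steiger.direction if self.steiger else "",
            p_steiger=self.steiger.pval if self.steiger else np.nan,
        )


def cochran_q(hset: pd.DataFrame, beta_ivw: float | None = None):
    """Cochran's Q heterogeneity statistic about the IVW fit.

    Q = sum_j (beta_out_j - beta_ivw * beta_exp_j)^2 / se_out_j^2, compared
    to chi-square with nsnp - 1 degrees of freedom.  ``beta_ivw`` defaults
    to the fixed-effect IVW estimate of the same set (the standard
    definition, whatever model is used for reporting).
    """
    n = len(hset)
    if n < 2:
        raise EstimatorError("Cochran's Q needs >= 2 records")
    if beta_ivw is None:
        beta_ivw = estimators.ivw(hset, "fixed").beta
    q = estimators.cochran_q_value(hset, beta_ivw)
    df = n - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def egger_intercept_test(hset: pd.DataFrame):
    """MR-Egger intercept, SE and two-sided t(nsnp-2) p-value."""
    res = estimators.mr_egger(hset)
    return res.intercept, res.intercept_se, res.intercept_pval


def leave_one_out(
    hset: pd.DataFrame, effects_model: str = "fixed", alpha: float = 0.05
) -> pd.DataFrame:
    """IVW excluding each SNP in turn.

    Returns one row per excluded SNP (beta, se, pval) plus ``flagged``:
    whether excluding that SNP flips the significance verdict at ``alpha``
    relative to the full-set IVW.  Two-record sets are permitted (each
    leave-one-out estimate is then the other SNP's Wald ratio) with a
    warning.
    """
    n = len(hset)
    if n < 2:
        raise EstimatorError("leave-one-out needs >= 2 records")
    if n == 2:
        estimators.logger.warning("leave_one_out on 2 records: each estimate is a Wald ratio")
    full = estimators.ivw(hset, effects_model)
    full_sig = full.pval < alpha
    rows = []
    for i in range(n):
        sub = hset.drop(hset.index[i])
        est = estimators.ivw(sub, effects_model)
        rows.append(
            dict(
                excluded_snp=hset.iloc[i]["snp"], beta=est.beta, se=est.se,
                pval=est.pval, flagged=(est.pval < alpha) != full_sig,
            )
        )
    return pd.DataFrame(rows)


def _r2_sum(beta: np.ndarray, se: np.ndarray, n: np.ndarray) -> float:
    t2 = (beta / se) ** 2
    r2 = t2 / (t2 + n - 2)
    return float(min(np.sum(r2), 1.0 - 1e-12))


def steiger_direction(hset: pd.DataFrame, alpha: float = 0.05) -> SteigerResult:
    """Directionality test comparing instrument r2 on the two sides.

    Per-SNP r2 is t^2/(t^2 + n - 2) on each side, summed over instruments;
    the aggregate correlations r = sqrt(r2) are compared with Fisher's
    z-transform: z = (atanh r_exp - atanh r_out) /
    sqrt(1/(n_exp - 3) + 1/(n_out - 3)).  Verdict "true" if the exposure
    side explains more variance with p < alpha, "false" if reversed with
    p < alpha, "uncertain" otherwise.
    """
    n_exp = hset["n_exp"].to_numpy(float)
    n_out = hset["n_out"].to_numpy(float)
    if np.any(n_exp <= 3) or np.any(n_out <= 3):
        raise EstimatorError("Steiger test needs n > 3 on both sides")
    r2_exp = _r2_sum(hset["beta_exp"].to_numpy(float), hset["se_exp"].to_numpy(float), n_exp)
    r2_out = _r2_sum(hset["beta_out"].to_numpy(float), hset["se_out"].to_numpy(float), n_out)
    ne, no = float(np.mean(n_exp)), float(np.mean(n_out))
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / np.sqrt(
        1.0 / (ne - 3.0) + 1.0 / (no - 3.0)
    )
    p = float(2.0 * stats.norm.sf(abs(z)))
    if p < alpha:
        direction = "true" if r2_exp > r2_out else "false"
    else:
        direction = "uncertain"
    return SteigerResult(direction, p, r2_exp, r2_out)


def funnel_scatter_data(hset: pd.DataFrame, estimates: list[MREstimate]):
    """Plot-ready funnel and scatter tables.

    Funnel: per-SNP ratio against its precision 1/se_ratio.  Scatter:
    per-SNP (beta_exp, beta_out) points with one fitted line per method
    (slope = that method's causal estimate; intercept nonzero only for
    MR-Egger).
    """
    if len(hset) == 0:
        raise EstimatorError("empty harmonized set")
    rs = estimators.ratio_set(hset)
    funnel = pd.DataFrame(
        {"snp": rs["snp"], "ratio": rs["ratio"], "precision": 1.0 / rs["se"]}
    )
    scatter = hset[["snp", "beta_exp", "se_exp", "beta_out", "se_out"]].copy()
    lines = []
    for e in estimates:
        intercept = 0.0
        if e.method == "MR Egger" and len(hset) >= 3:
            intercept = estimators.mr_egger(hset).intercept
        lines.append(dict(method=e.method, slope=e.beta, intercept=intercept))
    return funnel, scatter, pd.DataFrame(lines)


def full_report(
    hset: pd.DataFrame,
    estimates: list[MREstimate] | None = None,
    effects_model: str = "fixed",
    alpha: float = 0.05,
) -> SensitivityReport:
    """All diagnostics applicable to the set size, in one report."""
    n = len(hset)
    if n >= 2:
        q, qdf, qp = cochran_q(hset)
    else:
        q, qdf, qp = 0.0, 0, 1.0
    rep = SensitivityReport(q_stat=q, q_df=qdf, q_pval=qp)
    if n >= 3:
        rep.egger_intercept, rep.egger_intercept_se, rep.egger_intercept_pval = (
            egger_intercept_test(hset)
        )
        rep.loo_estimates = leave_one_out(hset, effects_model, alpha)
    rep.steiger = steiger_direction(hset, alpha)
    if estimates:
        rep.funnel_points, rep.scatter_points, rep.scatter_lines = funnel_scatter_data(
            hset, estimates
        )
    return rep
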