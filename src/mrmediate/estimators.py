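"""Summary-statistic MR causal-effect estimators.

Given a harmonized set {(beta_exp_j, se_exp_j, beta_out_j, se_out_j)} the
suite provides:

* Wald ratio (single instrument): beta_out / beta_exp with the first-order
  delta-method SE se_out / |beta_exp| (second-order optional);
* IVW: inverse-variance-weighted regression of outcome on exposure effects
  through the origin, with fixed or multiplicative random-effects SEs;
* MR-Egger: the same weighted regression with a free intercept (the
  intercept estimates average directional pleiotropy);
* weighted median: consistent when instruments carrying more than half of
  the weight are valid; SE by seeded parametric bootstrap;
* simple / weighted mode: kernel-density mode of the per-SNP ratios.

p-values are two-sided normal except MR-Egger, which uses t with nsnp-2
degrees of freedom.  For binary outcomes estimates are log odds ratios;
``estimates_to_table`` adds the exponentiated OR columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import logger

Z95 = 1.96


class EstimatorError(RuntimeError):
    """Degenerate input for an estimator (too few records, zero betas)."""


@dataclass
class MREstimate:
    """One method's causal-effect estimate (a row of the results table)."""

    method: str
    nsnp: int
    beta: float
    se: float
    pval: float
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    or_scale: bool = False

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if np.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def _arrays(hset: pd.DataFrame):
    bx = hset["beta_exp"].to_numpy(float)
    sx = hset["se_exp"].to_numpy(float)
    by = hset["beta_out"].to_numpy(float)
    sy = hset["se_out"].to_numpy(float)
    return bx, sx, by, sy


def ratio_set(hset: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP Wald ratios, first-order SEs and inverse-variance weights."""
    bx, _, by, sy = _arrays(hset)
    if np.any(bx == 0):
        raise EstimatorError("zero exposure beta in ratio computation")
    ratio = by / bx
    se = sy / np.abs(bx)
    return pd.DataFrame({"snp": hset["snp"], "ratio": ratio, "se": se, "weight": 1.0 / se**2})


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 1.0


def wald_ratio(h: pd.Series | pd.DataFrame, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    ``second_order=True`` adds the next delta-method term:
    se^2 = se_out^2/bx^2 + by^2 se_exp^2 / bx^4.
    """
    if isinstance(h, pd.DataFrame):
        if len(h) != 1:
            raise EstimatorError("wald_ratio takes exactly one record")
        h = h.iloc[0]
    bx, sx = float(h["beta_exp"]), float(h["se_exp"])
    by, sy = float(h["beta_out"]), float(h["se_out"])
    if bx == 0:
        raise EstimatorError("wald_ratio undefined for beta_exp = 0")
    beta = by / bx
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / abs(bx)
    z = beta / se
    return MREstimate("Wald ratio", 1, beta, float(se), _normal_p(z))


def cochran_q_value(hset: pd.DataFrame, beta: float) -> float:
    """Q = sum_j (beta_out_j - beta * beta_exp_j)^2 / se_out_j^2."""
    bx, _, by, sy = _arrays(hset)
    return float(np.sum((by - beta * bx) ** 2 / sy**2))


def ivw(hset: pd.DataFrame, effects_model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate (regression through the origin).

    beta = sum(bx by / sy^2) / sum(bx^2 / sy^2); the fixed-effect SE is
    (sum bx^2/sy^2)^(-1/2); the multiplicative random-effects SE inflates
    it by max(1, sqrt(Q/(nsnp-1))).  A single record delegates to the Wald
    ratio.
    """
    if effects_model not in ("fixed", "random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    if len(hset) == 0:
        raise EstimatorError("empty harmonized set")
    if len(hset) == 1:
        return wald_ratio(hset)
    bx, _, by, sy = _arrays(hset)
    if np.all(bx == 0):
        raise EstimatorError("all exposure betas are zero")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = denom ** -0.5
    if effects_model == "random":
        q = cochran_q_value(hset, beta)
        se *= max(1.0, np.sqrt(q / (len(hset) - 1)))
    return MREstimate("IVW", len(hset), beta, se, _normal_p(beta / se))


def mr_egger(hset: pd.DataFrame) -> EggerResult:
    """MR-Egger weighted regression with intercept.

    Records are oriented so beta_exp >= 0 (both sides negated where
    needed); weights 1/se_out^2; SEs carry the multiplicative
    random-effects inflation max(1, sqrt(RSS/(nsnp-2))); p-values use
    t(nsnp-2).
    """
    n = len(hset)
    if n < 3:
        raise EstimatorError("insufficient instruments for Egger (need >= 3)")
    bx, _, by, sy = _arrays(hset)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    sw, swx, swx2 = np.sum(w), np.sum(w * x), np.sum(w * x * x)
    swy, swxy = np.sum(w * y), np.sum(w * x * y)
    delta = sw * swx2 - swx**2
    if delta <= 0:
        raise EstimatorError("degenerate design in Egger regression")
    slope = (sw * swxy - swx * swy) / delta
    intercept = (swy * swx2 - swx * swxy) / delta
    rss = float(np.sum(w * (y - intercept - slope * x) ** 2))
    scale = max(1.0, rss / (n - 2))
    se_slope = np.sqrt(sw / delta * scale)
    se_int = np.sqrt(swx2 / delta * scale)
    df = n - 2
    p_slope = float(2.0 * stats.t.sf(abs(slope / se_slope), df))
    p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), df))
    tcrit = float(stats.t.ppf(0.975, df))
    est = MREstimate(
        "MR Egger", n, float(slope), float(se_slope), p_slope,
        ci_low=float(slope - tcrit * se_slope), ci_high=float(slope + tcrit * se_slope),
    )
    return EggerResult(est, float(intercept), float(se_int), p_int)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median at standardized cumulative weight 0.5."""
    order = np.argsort(ratios, kind="mergesort")
    b = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, b))


def weighted_median(
    hset: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator (valid if >50% of the weight is valid).

    SE by parametric bootstrap: exposure and outcome betas are resampled
    from their normal sampling distributions ``n_boot`` times (seeded) and
    the SD of the recomputed medians is reported.
    """
    n = len(hset)
    if n < 3:
        raise EstimatorError("weighted median needs >= 3 instruments")
    rs = ratio_set(hset)
    beta = _weighted_median_point(rs["ratio"].to_numpy(), rs["weight"].to_numpy())
    bx, sx, by, sy = _arrays(hset)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ok = bxs != 0
        r = bys[ok] / bxs[ok]
        se_r = sy[ok] / np.abs(bxs[ok])
        boots[i] = _weighted_median_point(r, 1.0 / se_r**2)
    se = float(np.std(boots, ddof=1))
    return MREstimate("Weighted median", n, beta, se, _normal_p(beta / se))


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    """Kernel-density mode of ratio estimates (Gaussian kernel, fine grid).

    Bandwidth follows the modified Silverman rule
    0.9 min(sd, mad) n^(-1/5), scaled by ``bandwidth_factor``.
    """
    n = len(ratios)
    sd = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    h = bandwidth_factor * 0.9 * min(sd, mad) / n ** 0.2 if min(sd, mad) > 0 else 0.0
    if h <= 0:
        # degenerate spread: fall back to the (weighted) median of a point mass
        return _weighted_median_point(ratios, weights)
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 2048)
    dens = (weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimator(
    hset: pd.DataFrame,
    variant: str = "simple",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: the densest cluster of per-SNP ratios.

    ``simple`` weights each ratio equally; ``weighted`` weights kernel
    contributions by inverse ratio variance.  SE by seeded parametric
    bootstrap, as for the weighted median.
    """
    if variant not in ("simple", "weighted"):
        raise ValueError(f"unknown mode variant {variant!r}")
    n = len(hset)
    if n < 3:
        raise EstimatorError("mode estimator needs >= 3 instruments")
    rs = ratio_set(hset)
    ratios = rs["ratio"].to_numpy()
    weights = rs["weight"].to_numpy() if variant == "weighted" else np.ones(n)
    beta = _mode_point(ratios, weights, bandwidth_factor)
    bx, sx, by, sy = _arrays(hset)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ok = bxs != 0
        r = bys[ok] / bxs[ok]
        w = 1.0 / (sy[ok] / np.abs(bxs[ok])) ** 2 if variant == "weighted" else np.ones(ok.sum())
        boots[i] = _mode_point(r, w, bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    name = "Simple mode" if variant == "simple" else "Weighted mode"
    return MREstimate(name, n, beta, se, _normal_p(beta / se))


def run_all_methods(
    hset: pd.DataFrame,
    effects_model: str = "fixed",
    n_boot: int = 1000,
    seed: int = 0,
    bandwidth_factor: float = 1.0,
) -> list[MREstimate]:
    """Run every applicable estimator on one harmonized set.

    With a single record only the Wald ratio applies; methods needing
    three or more records are skipped (logged) on two-record sets.
    Output order mirrors the conventional results-table layout:
    MR-Egger, weighted median, IVW, simple mode, weighted mode.
    """
    n = len(hset)
    if n == 0:
        raise EstimatorError("empty harmonized set")
    if n == 1:
        return [wald_ratio(hset)]
    out: list[MREstimate] = []
    if n >= 3:
        out.append(mr_egger(hset).slope)
        out.append(weighted_median(hset, n_boot=n_boot, seed=seed))
    else:
        logger.info("run_all_methods: %d record(s); Egger/median/mode skipped", n)
    out.append(ivw(hset, effects_model=effects_model))
    if n >= 3:
        out.append(mode_estimator(hset, "simple", bandwidth_factor, n_boot, seed + 1))
        out.append(mode_estimator(hset, "weighted", bandwidth_factor, n_boot, seed + 2))
    return out


def estimates_to_table(estimates: list[MREstimate], binary_outcome: bool = False) -> pd.DataFrame:
    """Tabulate estimates; for binary outcomes add exponentiated OR columns."""
    rows = []
    for e in estimates:
        row = dict(
            method=e.method, nsnp=e.nsnp, beta=e.beta, se=e.se, pval=e.pval,
            ci_low=e.ci_low, ci_high=e.ci_high,
        )
        if binary_outcome:
            row["or"] = float(np.exp(e.beta))
            row["or_ci_low"] = float(np.exp(e.ci_low))
            row["or_ci_high"] = float(np.exp(e.ci_high))
        rows.append(row)
    return pd.DataFrame(rows)
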