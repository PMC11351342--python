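"""Two-step MR mediation: screening cascades and the Sobel statistic.

The indirect (mediated) effect of an exposure on an outcome through a
mediator is the product of coefficients b1 * b2, where b1 is the MR effect
exposure -> mediator and b2 the MR effect mediator -> outcome.  Its Sobel
standard error is S = sqrt(b1^2 s2^2 + b2^2 s1^2), giving Z = b1 b2 / S and
a symmetric 95% CI b1 b2 +/- 1.96 S.

Mediators enter the Sobel stage only after a two-step screen:

* step 1 (exposure -> mediator): IVW p < alpha AND 2SLS p < alpha, and no
  evidence of horizontal pleiotropy (Egger-intercept p >= alpha);
* step 2 (mediator -> outcome): Wald-ratio/IVW p < alpha, no heterogeneity
  (Q p >= alpha), and a Steiger verdict of "true";
* final: both screens passed and Sobel p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z95


@dataclass
class MediationResult:
    """Product-of-coefficients mediation estimate for one mediator."""

    mediator_id: str
    b1: float
    s1: float
    b2: float
    s2: float
    indirect: float
    sobel_se: float
    z_stat: float
    pval: float
    ci_low: float
    ci_high: float
    total_effect: float = np.nan
    direct_effect: float = np.nan
    proportion_mediated: float = np.nan


@dataclass
class ScreeningVerdict:
    mediator_id: str
    step1_pass: bool
    step1_reason: str
    step2_pass: bool = False
    step2_reason: str = ""
    final_pass: bool = False


def sobel_mediation(
    b1: float,
    s1: float,
    b2: float,
    s2: float,
    total_effect: float | None = None,
    mediator_id: str = "",
    printed_linear_se: bool = False,
) -> MediationResult:
    """Sobel test of the indirect effect b1 * b2.

    ``printed_linear_se=True`` switches to the additive compatibility form
    S = b1*s2 + b2*s1 (no squares or root); it is not a valid standard
    error under rescaling and exists only for comparison, never as the
    default.  ``total_effect``, when given, yields the direct effect
    (total - indirect) and the unconstrained proportion mediated
    (indirect / total; may lie outside [0, 1] when signs oppose).
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("s1 and s2 must be positive")
    indirect = b1 * b2
    if printed_linear_se:
        s = b1 * s2 + b2 * s1
    else:
        s = float(np.sqrt(b1**2 * s2**2 + b2**2 * s1**2))
    if s == 0:
        z, p = 0.0, 1.0  # only reachable when b1 = b2 = 0
    else:
        z = indirect / s
        p = float(2.0 * stats.norm.sf(abs(z)))
    res = MediationResult(
        mediator_id=mediator_id, b1=b1, s1=s1, b2=b2, s2=s2,
        indirect=indirect, sobel_se=s, z_stat=z, pval=p,
        ci_low=indirect - Z95 * s, ci_high=indirect + Z95 * s,
    )
    if total_effect is not None:
        res.total_effect = total_effect
        res.direct_effect = total_effect - indirect
        res.proportion_mediated = indirect / total_effect if total_effect != 0 else np.nan
    return res


def _get(run: dict, key: str):
    v = run.get(key)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return v


def screen_step1(
    step1_runs: dict[str, dict], alpha: float = 0.05, require_tsls: bool = True
) -> dict[str, ScreeningVerdict]:
    """Step-1 screen: exposure causally affects the mediator, cleanly.

    Per mediator the run dict carries ``ivw_pval``, ``tsls_pval`` and
    ``pleiotropy_pval`` (Egger intercept).  Pass iff ivw_pval < alpha AND
    tsls_pval < alpha AND pleiotropy_pval >= alpha.  When
    ``require_tsls=False`` (no individual-level data available) the 2SLS
    criterion is waived.  The reason string records the first failing rule.
    """
    verdicts: dict[str, ScreeningVerdict] = {}
    for mid, run in step1_runs.items():
        ivw_p = _get(run, "ivw_pval")
        tsls_p = _get(run, "tsls_pval")
        ple_p = _get(run, "pleiotropy_pval")
        if ivw_p is None or ple_p is None or (require_tsls and tsls_p is None):
            verdicts[mid] = ScreeningVerdict(mid, False, "incomplete")
            continue
        if not ivw_p < alpha:
            ok, reason = False, "ivw not significant"
        elif require_tsls and not tsls_p < alpha:
            ok, reason = False, "2sls not significant"
        elif not ple_p >= alpha:
            ok, reason = False, "pleiotropy"
        else:
            ok, reason = True, "pass"
        verdicts[mid] = ScreeningVerdict(mid, ok, reason)
    return verdicts


def screen_step2(
    step2_runs: dict[str, dict],
    verdicts: dict[str, ScreeningVerdict],
    alpha: float = 0.05,
) -> dict[str, ScreeningVerdict]:
    """Step-2 screen: mediator causally affects the outcome, cleanly.

    Per mediator: ``effect_pval`` (Wald ratio or IVW), ``het_pval``
    (Cochran Q) and ``steiger`` ("true"/"false"/"uncertain").  Pass iff
    effect_pval < alpha AND het_pval >= alpha AND steiger == "true".
    Verdicts are updated in place for mediators present in both maps.
    """
    for mid, run in step2_runs.items():
        v = verdicts.setdefault(mid, ScreeningVerdict(mid, False, "no step-1 run"))
        eff_p = _get(run, "effect_pval")
        het_p = _get(run, "het_pval")
        steiger = run.get("steiger")
        if eff_p is None or het_p is None or steiger is None:
            v.step2_pass, v.step2_reason = False, "incomplete"
            continue
        if not eff_p < alpha:
            v.step2_pass, v.step2_reason = False, "effect not significant"
        elif not het_p >= alpha:
            v.step2_pass, v.step2_reason = False, "heterogeneity"
        elif steiger != "true":
            v.step2_pass, v.step2_reason = False, "direction"
        else:
            v.step2_pass, v.step2_reason = True, "pass"
    return verdicts


_TABLE_COLUMNS = [
    "mediator_id", "region", "phenotype", "method",
    "b1", "s1", "b2", "s2", "indirect", "sobel_se", "z", "pval",
    "ci_low", "ci_high", "proportion", "final_pass", "reason",
]


def _split_id(mediator_id: str) -> tuple[str, str]:
    """``region:phenotype`` convention; bare ids map to region=id."""
    if ":" in mediator_id:
        region, phen = mediator_id.split(":", 1)
        return region, phen
    return mediator_id, ""


def assemble_mediation_table(
    verdicts: dict[str, ScreeningVerdict],
    mediation_results: dict[str, MediationResult],
    alpha: float = 0.05,
    methods: dict[str, str] | None = None,
    multiple_testing: str = "none",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Final mediation table plus the per-region summary.

    ``final_pass`` requires both screens and Sobel p < alpha.  Rows are
    sorted by mediator region then phenotype.  The summary table gives
    per-region mean indirect effect and mean Sobel p over passing
    mediators.

    ``multiple_testing="bh"`` applies Benjamini-Hochberg control across
    the Sobel p-values of screen survivors before the alpha comparison —
    an extension to the nominal-threshold default, off unless requested.
    """
    if multiple_testing not in ("none", "bh"):
        raise ValueError(f"unknown multiple_testing mode {multiple_testing!r}")
    adjusted: dict[str, float] = {
        mid: res.pval for mid, res in mediation_results.items()
    }
    if multiple_testing == "bh":
        eligible = [
            mid for mid, v in verdicts.items()
            if v.step1_pass and v.step2_pass and mid in mediation_results
        ]
        if eligible:
            qvals = stats.false_discovery_control(
                [mediation_results[m].pval for m in eligible], method="bh"
            )
            adjusted.update(dict(zip(eligible, (float(q) for q in qvals))))
    rows = []
    for mid, v in sorted(verdicts.items()):
        region, phen = _split_id(mid)
        res = mediation_results.get(mid)
        passed = bool(
            v.step1_pass and v.step2_pass and res is not None
            and adjusted[mid] < alpha
        )
        v.final_pass = passed
        if not v.step1_pass:
            reason = f"step1: {v.step1_reason}"
        elif not v.step2_pass:
            reason = f"step2: {v.step2_reason}"
        elif res is None:
            reason = "no mediation estimate"
        elif not passed:
            reason = "sobel not significant"
        else:
            reason = "pass"
        row = dict(
            mediator_id=mid, region=region, phenotype=phen,
            method=(methods or {}).get(mid, ""),
            final_pass=passed, reason=reason,
        )
        if res is not None:
            row.update(
                b1=res.b1, s1=res.s1, b2=res.b2, s2=res.s2,
                indirect=res.indirect, sobel_se=res.sobel_se, z=res.z_stat,
                pval=res.pval, ci_low=res.ci_low, ci_high=res.ci_high,
                proportion=res.proportion_mediated,
            )
        rows.append(row)
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    table = table.sort_values(["region", "phenotype"], kind="mergesort").reset_index(drop=True)
    passed = table.loc[table["final_pass"]]
    if len(passed):
        summary = (
            passed.groupby("region", sort=True)
            .agg(
                n_mediators=("mediator_id", "size"),
                mean_indirect=("indirect", "mean"),
                mean_pval=("pval", "mean"),
            )
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["region", "n_mediators", "mean_indirect", "mean_pval"])
    return table, summary
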