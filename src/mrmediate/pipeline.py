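"""Study orchestration: bidirectional MR and the two-step mediation scan.

``run_bidirectional`` performs the full instrument-selection cascade and
estimator/sensitivity suite exposure -> outcome and, with roles swapped,
outcome -> exposure.  ``run_two_step`` adds the mediator layer: a step-1
exposure -> mediator run (IVW plus 2SLS when individual-level synthetic
data is available), a step-2 mediator -> outcome run with heterogeneity
and Steiger screening, and the Sobel product-of-coefficients statistic for
survivors.  Every filter records its in/out counts so that stage counts
are conserved and auditable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import instruments, mediation, sensitivity
from .estimators import MREstimate, estimates_to_table, run_all_methods
from .gwas_io import GwasIOError, SummaryStatTable, harmonize_pair, logger
from .instruments import LDMatrix
from .mediation import ScreeningVerdict
from .sensitivity import SensitivityReport
from .synthetic import Cohort, two_stage_least_squares


class SelfMRError(GwasIOError):
    """Exposure and outcome are the same table (self-MR is undefined)."""


@dataclass
class RunConfig:
    """All thresholds and paths of one pipeline invocation."""

    p_threshold: float = 5e-8
    outcome_p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    f_min: float = 10.0
    alpha: float = 0.05
    palindromic_policy: str = "drop"
    eaf_window: float = 0.08
    effects_model_policy: str = "auto_by_q"   # {auto_by_q, fixed, random}
    n_boot: int = 1000
    seed: int = 0
    confounder_traits: list[str] = field(default_factory=list)
    # input paths (optional; the Python API passes objects directly)
    exposure: str | None = None
    outcome: str | None = None
    mediators: list[str] = field(default_factory=list)
    ld: str | None = None
    confounders: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("p_threshold", "outcome_p_threshold", "clump_r2", "clump_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effects_model_policy not in ("auto_by_q", "fixed", "random"):
            raise ValueError(f"unknown effects_model_policy {self.effects_model_policy!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


class FilterLog:
    """Per-stage instrument counts; conservation is asserted, not assumed."""

    def __init__(self) -> None:
        self.entries: list[dict] = []

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        self.entries.append(
            dict(stage=stage, n_in=int(n_in), n_out=int(n_out), n_dropped=int(n_in - n_out))
        )

    def assert_conserved(self) -> None:
        for e in self.entries:
            if e["n_in"] != e["n_out"] + e["n_dropped"]:
                raise AssertionError(f"filter log not conserved at {e['stage']}: {e}")
        for prev, nxt in zip(self.entries, self.entries[1:]):
            if prev["n_out"] != nxt["n_in"]:
                raise AssertionError(
                    f"stage chaining broken: {prev['stage']} out {prev['n_out']} != "
                    f"{nxt['stage']} in {nxt['n_in']}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["stage", "n_in", "n_out", "n_dropped"])


@dataclass
class MRRunResult:
    """One exposure -> outcome MR run with diagnostics."""

    exposure_id: str
    outcome_id: str
    estimable: bool
    instruments: pd.DataFrame | None = field(default=None, repr=False)
    harmonized: pd.DataFrame | None = field(default=None, repr=False)
    estimates: list[MREstimate] = field(default_factory=list, repr=False)
    estimates_table: pd.DataFrame | None = field(default=None, repr=False)
    sensitivity: SensitivityReport | None = field(default=None, repr=False)
    filter_log: FilterLog = field(default_factory=FilterLog, repr=False)
    effects_model: str = "fixed"

    def primary(self) -> MREstimate | None:
        """The headline estimate: IVW, or the Wald ratio for a single IV."""
        for e in self.estimates:
            if e.method == "IVW":
                return e
        for e in self.estimates:
            if e.method == "Wald ratio":
                return e
        return None


def _check_not_self(exposure: SummaryStatTable, outcome: SummaryStatTable) -> None:
    if exposure.trait_id == outcome.trait_id:
        raise SelfMRError(f"exposure and outcome are the same trait {exposure.trait_id!r}")
    if len(exposure.records) == len(outcome.records) and exposure.records.equals(outcome.records):
        raise SelfMRError("exposure and outcome tables are identical (self-MR)")


def single_mr_run(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    config: RunConfig,
    ld: LDMatrix | None = None,
    confounder_lookup: pd.DataFrame | None = None,
    exclude_snps: set[str] | None = None,
    exclusion_outcome: SummaryStatTable | None = None,
) -> MRRunResult:
    """Instrument selection -> harmonization -> estimators -> sensitivity.

    ``exclude_snps`` removes named SNPs right after the significance
    filter; the two-step scan uses it so that step-2 mediator runs rely on
    the mediator's own instruments rather than SNPs borrowed from the
    exposure (which reach the outcome through every other mediator).

    ``exclusion_outcome`` overrides the table used for the
    outcome-association exclusion.  The two-step scan screens step-1
    instruments against the disease outcome rather than the mediator:
    dropping instruments for being associated with a trait the exposure
    causally drives would delete the very signal under test.
    """
    _check_not_self(exposure, outcome)
    flog = FilterLog()
    n0 = exposure.n_snps
    inst = instruments.select_genomewide(exposure, config.p_threshold)
    flog.record("genomewide_significance", n0, len(inst))
    if exclude_snps:
        n_in = len(inst)
        inst = inst.loc[~inst["snp"].isin(exclude_snps)].reset_index(drop=True)
        flog.record("named_snp_exclusion", n_in, len(inst))
    if ld is not None and len(inst):
        n_in = len(inst)
        inst = instruments.ld_clump(
            inst, ld, r2_threshold=config.clump_r2, window_kb=config.clump_kb
        )
        flog.record("ld_clump", n_in, len(inst))
    if len(inst):
        n_in = len(inst)
        inst = instruments.exclude_outcome_associated(
            inst, exclusion_outcome if exclusion_outcome is not None else outcome,
            config.outcome_p_threshold,
        )
        flog.record("outcome_association", n_in, len(inst))
    if len(inst):
        n_in = len(inst)
        inst = instruments.exclude_listed_confounders(
            inst, confounder_lookup, config.confounder_traits
        )
        flog.record("confounder_exclusion", n_in, len(inst))
    if len(inst):
        n_in = len(inst)
        inst = instruments.compute_f_statistics(inst)
        inst = instruments.filter_weak_instruments(inst, config.f_min)
        flog.record("weak_instrument_filter", n_in, len(inst))
    result = MRRunResult(
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
        estimable=False, instruments=inst, filter_log=flog,
    )
    if len(inst) == 0:
        logger.warning(
            "no instruments survive selection for %s -> %s: not estimable",
            exposure.trait_id, outcome.trait_id,
        )
        return result
    exp_sub = SummaryStatTable(
        trait_id=exposure.trait_id, trait_type=exposure.trait_type,
        records=inst[[c for c in exposure.records.columns]],
    )
    hset = harmonize_pair(
        exp_sub, outcome,
        palindromic_policy=config.palindromic_policy, eaf_window=config.eaf_window,
    )
    flog.record("harmonization", len(inst), len(hset))
    result.harmonized = hset
    if len(hset) == 0:
        return result

    effects_model = config.effects_model_policy
    if effects_model == "auto_by_q":
        if len(hset) >= 2:
            _, _, qp = sensitivity.cochran_q(hset)
            effects_model = "random" if qp < config.alpha else "fixed"
        else:
            effects_model = "fixed"
    result.effects_model = effects_model
    result.estimates = run_all_methods(
        hset, effects_model=effects_model, n_boot=config.n_boot, seed=config.seed
    )
    result.estimates_table = estimates_to_table(
        result.estimates, binary_outcome=outcome.trait_type == "binary"
    )
    result.sensitivity = sensitivity.full_report(
        hset, result.estimates, effects_model=effects_model, alpha=config.alpha
    )
    result.estimable = True
    return result


@dataclass
class BidirectionalReport:
    forward: MRRunResult
    reverse: MRRunResult


def run_bidirectional(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    config: RunConfig,
    ld: LDMatrix | None = None,
    confounder_lookup: pd.DataFrame | None = None,
) -> BidirectionalReport:
    """Forward and role-swapped reverse MR under identical selection rules."""
    forward = single_mr_run(exposure, outcome, config, ld, confounder_lookup)
    reverse = single_mr_run(outcome, exposure, config, ld, confounder_lookup)
    return BidirectionalReport(forward=forward, reverse=reverse)


@dataclass
class StudyReport:
    """Everything one two-step invocation produces, as plain tables."""

    config: RunConfig
    forward: MRRunResult
    reverse: MRRunResult | None
    step1: pd.DataFrame
    step2: pd.DataFrame
    mediation_table: pd.DataFrame
    region_summary: pd.DataFrame
    verdicts: dict[str, ScreeningVerdict] = field(default_factory=dict, repr=False)
    step1_runs: dict[str, MRRunResult] = field(default_factory=dict, repr=False)
    step2_runs: dict[str, MRRunResult] = field(default_factory=dict, repr=False)

    def provenance(self) -> dict:
        stages = {}
        runs = {"forward": self.forward}
        if self.reverse is not None:
            runs["reverse"] = self.reverse
        runs.update({f"step1:{k}": v for k, v in self.step1_runs.items()})
        runs.update({f"step2:{k}": v for k, v in self.step2_runs.items()})
        for name, run in runs.items():
            run.filter_log.assert_conserved()
            stages[name] = run.filter_log.entries
        return {
            "package": "mrmediate",
            "version": __version__,
            "seed": self.config.seed,
            "config": dataclasses.asdict(self.config),
            "stage_counts": stages,
        }

    def write(self, outdir) -> None:
        """Serialize all tables under ``outdir`` (deterministic formatting)."""
        out = Path(outdir)
        tables = out / "tables"
        tables.mkdir(parents=True, exist_ok=True)

        def _w(df: pd.DataFrame | None, name: str) -> None:
            if df is not None:
                df.to_csv(tables / name, sep="\t", index=False, float_format="%.12g")

        _w(self.forward.estimates_table, "forward_estimates.tsv")
        if self.reverse is not None:
            _w(self.reverse.estimates_table, "reverse_estimates.tsv")
        _w(self.step1, "step1.tsv")
        _w(self.step2, "step2.tsv")
        _w(self.mediation_table, "mediation.tsv")
        _w(self.region_summary, "region_summary.tsv")
        sens_rows = []
        for label, run in [("forward", self.forward), ("reverse", self.reverse)]:
            if run is not None and run.sensitivity is not None:
                sens_rows.append(dict(run=label, **run.sensitivity.summary_row()))
        if sens_rows:
            _w(pd.DataFrame(sens_rows), "sensitivity.tsv")
        if self.forward.sensitivity is not None:
            _w(self.forward.sensitivity.loo_estimates, "loo.tsv")
            _w(self.forward.sensitivity.funnel_points, "funnel.tsv")
            _w(self.forward.sensitivity.scatter_points, "scatter.tsv")
            _w(self.forward.sensitivity.scatter_lines, "scatter_lines.tsv")
        with open(out / "provenance.txt", "w") as fh:
            json.dump(self.provenance(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "log.txt", "w") as fh:
            for name, entries in self.provenance()["stage_counts"].items():
                for e in entries:
                    fh.write(
                        f"{name}\t{e['stage']}\t{e['n_in']}\t{e['n_out']}\t{e['n_dropped']}\n"
                    )


def _step1_tsls(
    cohort: Cohort, mediator_id: str, instrument_snps: list[str]
) -> tuple[float, float, float]:
    """2SLS of mediator on exposure in the mediator-role sub-cohort."""
    k = cohort.mediator_names.index(mediator_id)
    g = cohort.genotype_matrix(instrument_snps, "mediator")
    idx = cohort.roles["mediator"]
    res = two_stage_least_squares(g, cohort.exposure[idx], cohort.mediators[idx, k])
    return res.pval, res.beta, res.stage1_r2


def run_two_step(
    exposure: SummaryStatTable,
    mediator_tables: list[SummaryStatTable],
    outcome: SummaryStatTable,
    config: RunConfig,
    ld: LDMatrix | None = None,
    confounder_lookup: pd.DataFrame | None = None,
    cohort: Cohort | None = None,
    bidirectional: bool = True,
) -> StudyReport:
    """The full two-step mediation scan.

    Per-mediator failures are isolated: a mediator whose step fails with an
    error is marked failed and the scan continues.  When ``cohort`` is
    given (synthetic individual-level data), step 1 enforces the dual
    IVW + 2SLS significance rule; otherwise the 2SLS criterion is waived
    with a log note.
    """
    if not mediator_tables:
        raise ValueError("run_two_step needs at least one mediator table")
    if bidirectional:
        bid = run_bidirectional(exposure, outcome, config, ld, confounder_lookup)
        forward, reverse = bid.forward, bid.reverse
    else:
        forward = single_mr_run(exposure, outcome, config, ld, confounder_lookup)
        reverse = None
    total = forward.primary()
    total_effect = total.beta if total is not None else None

    require_tsls = cohort is not None
    if not require_tsls:
        logger.info("run_two_step: no individual-level cohort; 2SLS criterion waived")
    # step-2 runs use the mediator's own instruments: SNPs that are
    # genome-wide instruments of the exposure are excluded there, since
    # they reach the outcome through paths other than this mediator
    exposure_gw = set(
        instruments.select_genomewide(exposure, config.p_threshold)["snp"]
    )
    step1_inputs: dict[str, dict] = {}
    step2_inputs: dict[str, dict] = {}
    step1_rows, step2_rows = [], []
    step1_runs: dict[str, MRRunResult] = {}
    step2_runs: dict[str, MRRunResult] = {}
    b_pairs: dict[str, tuple[float, float, float, float]] = {}

    for i_med, med in enumerate(mediator_tables):
        mid = med.trait_id
        cohort_key = None
        if cohort is not None:
            if mid in cohort.mediator_names:
                cohort_key = mid
            elif len(mediator_tables) == len(cohort.mediator_names):
                cohort_key = cohort.mediator_names[i_med]  # positional match
            else:
                logger.warning("mediator %s not found in cohort; 2SLS skipped", mid)
        try:
            s1 = single_mr_run(
                exposure, med, config, ld, confounder_lookup,
                exclusion_outcome=outcome,
            )
            step1_runs[mid] = s1
            if not s1.estimable:
                step1_inputs[mid] = {}
                step1_rows.append(dict(mediator_id=mid, estimable=False))
                continue
            p1 = s1.primary()
            tsls_pval = tsls_beta = tsls_r2 = np.nan
            if cohort_key is not None:
                snps = list(s1.harmonized["snp"])
                tsls_pval, tsls_beta, tsls_r2 = _step1_tsls(cohort, cohort_key, snps)
            ple_p = s1.sensitivity.egger_intercept_pval if s1.sensitivity else np.nan
            step1_inputs[mid] = dict(
                ivw_pval=p1.pval, tsls_pval=tsls_pval, pleiotropy_pval=ple_p
            )
            step1_rows.append(
                dict(
                    mediator_id=mid, estimable=True, nsnp=p1.nsnp,
                    b1=p1.beta, s1=p1.se, ivw_pval=p1.pval,
                    tsls_pval=tsls_pval, tsls_beta=tsls_beta, tsls_r2=tsls_r2,
                    p_het=s1.sensitivity.q_pval, p_ple=ple_p,
                )
            )

            s2 = single_mr_run(
                med, outcome, config, ld, confounder_lookup, exclude_snps=exposure_gw
            )
            step2_runs[mid] = s2
            if not s2.estimable:
                step2_inputs[mid] = {}
                step2_rows.append(dict(mediator_id=mid, estimable=False))
                continue
            p2 = s2.primary()
            steiger = s2.sensitivity.steiger.direction if s2.sensitivity.steiger else None
            step2_inputs[mid] = dict(
                effect_pval=p2.pval,
                method="wald" if p2.method == "Wald ratio" else "ivw",
                het_pval=s2.sensitivity.q_pval,
                steiger=steiger,
            )
            step2_rows.append(
                dict(
                    mediator_id=mid, estimable=True, nsnp=p2.nsnp,
                    b2=p2.beta, s2=p2.se, effect_pval=p2.pval, method=p2.method,
                    p_het=s2.sensitivity.q_pval,
                    p_ple=s2.sensitivity.egger_intercept_pval,
                    steiger=steiger,
                    p_steiger=s2.sensitivity.steiger.pval if s2.sensitivity.steiger else np.nan,
                )
            )
            b_pairs[mid] = (p1.beta, p1.se, p2.beta, p2.se)
        except Exception as exc:  # failure isolation: one mediator cannot abort the scan
            logger.error("mediator %s failed: %s", mid, exc)
            step1_inputs.setdefault(mid, {})
            step1_rows.append(dict(mediator_id=mid, estimable=False, error=str(exc)))

    verdicts = mediation.screen_step1(step1_inputs, config.alpha, require_tsls=require_tsls)
    verdicts = mediation.screen_step2(step2_inputs, verdicts, config.alpha)
    med_results = {}
    for mid, (b1, s1_, b2, s2_) in b_pairs.items():
        med_results[mid] = mediation.sobel_mediation(
            b1, s1_, b2, s2_, total_effect=total_effect, mediator_id=mid
        )
    methods = {mid: run.get("method", "") for mid, run in step2_inputs.items()}
    table, summary = mediation.assemble_mediation_table(
        verdicts, med_results, config.alpha, methods=methods
    )
    return StudyReport(
        config=config, forward=forward, reverse=reverse,
        step1=pd.DataFrame(step1_rows), step2=pd.DataFrame(step2_rows),
        mediation_table=table, region_summary=summary,
        verdicts=verdicts, step1_runs=step1_runs, step2_runs=step2_runs,
    )
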