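"""Synthetic GWAS cohorts with known causal structure.

Generates individual-level data for a polygenic continuous exposure X, one
or more continuous mediators M_k and a binary outcome Y, then derives GWAS
summary statistics from three disjoint sub-cohorts (exposure, mediator and
outcome GWAS roles), emulating non-overlapping two-sample designs.

Structural model (forward scenarios)::

    X   = sum_j a_j G_j + e_x                     (instrument block)
    M_k = theta1_k X + sum_j b_kj G_kj            (own-SNP block)
          + sum_j gamma_kj G_j + e_mk             (pleiotropy on X's SNPs)
    L   = delta X + sum_k theta2_k M_k
          + sum_kj gy_kj G_kj                     (step-2 heterogeneity)
    Y   = threshold(L) at a target prevalence

The binary outcome thresholds a logistic-residual liability (exactly a
logistic link, so per-SNP log-odds GWAS effects match the theta2 log-odds
scale up to noncollapsibility), or optionally a Gaussian-residual probit
liability.  Reverse scenarios flip the exposure-mediator arrow: the
instrument block acts on M and X = theta1 M + e.

The module also provides the 2SLS estimator used alongside IVW in step-1
screening, and named scenario presets with fully seeded configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

from .gwas_io import SummaryStatTable, CANONICAL_COLUMNS, logger
from .instruments import LDMatrix

_ALLELE_PAIRS = [  # non-palindromic pairs only: simulated studies share strand
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]


class ScenarioError(ValueError):
    """Infeasible or unknown scenario configuration."""


@dataclass
class MediatorSpec:
    """Causal wiring of one mediator phenotype."""

    name: str = "mediator"
    theta1: float = 0.0          # exposure -> mediator
    theta2: float = 0.0          # mediator -> outcome, log-odds per unit
    own_h2: float = 0.15         # mediator variance from its own SNP block
    n_own_snps: int = 30
    pleiotropy: str = "none"     # {none, balanced, directional} on X's SNPs
    pleiotropy_frac: float = 0.3
    pleiotropy_scale: float = 0.04
    het_scale: float = 0.0       # sd of own-SNP direct effects on liability


@dataclass
class ScenarioConfig:
    """Full specification of one simulated study."""

    n_per_cohort: int = 20_000
    n_snps: int = 50                      # exposure instrument block
    maf_range: tuple[float, float] = (0.1, 0.5)
    exposure_h2: float = 0.2
    theta1: float = 0.0
    theta2: float = 0.0
    delta_direct: float = 0.0
    own_h2: float = 0.15
    n_own_snps: int = 30
    pleiotropy: str = "none"
    pleiotropy_frac: float = 0.3
    pleiotropy_scale: float = 0.04
    het_scale: float = 0.0
    mediators: list[MediatorSpec] | None = None   # multi-mediator override
    ld_blocks: tuple[int, float] | None = None    # (block size, within-block r2)
    outcome_prevalence: float = 0.05
    liability_link: str = "logistic"              # or "probit"
    reverse: bool = False
    overlap_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ScenarioError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if not 0 <= self.exposure_h2 < 1:
            raise ScenarioError("exposure_h2 must be in [0, 1)")
        if not 0 < self.outcome_prevalence < 1:
            raise ScenarioError("outcome_prevalence must be in (0, 1)")
        if self.liability_link not in ("logistic", "probit"):
            raise ScenarioError(f"unknown liability_link {self.liability_link!r}")

    def mediator_specs(self) -> list[MediatorSpec]:
        if self.mediators is not None:
            return self.mediators
        return [
            MediatorSpec(
                name="mediator", theta1=self.theta1, theta2=self.theta2,
                own_h2=self.own_h2, n_own_snps=self.n_own_snps,
                pleiotropy=self.pleiotropy, pleiotropy_frac=self.pleiotropy_frac,
                pleiotropy_scale=self.pleiotropy_scale, het_scale=self.het_scale,
            )
        ]


@dataclass
class CohortTruth:
    """Realized generative parameters (the ground truth for recovery tests)."""

    a: np.ndarray                       # instrument-block effects on exposure
    b: list[np.ndarray]                 # per-mediator own-SNP effects
    gamma: list[np.ndarray]             # per-mediator pleiotropy on X's SNPs
    gamma_y: list[np.ndarray]           # per-mediator own-SNP liability effects
    theta1: np.ndarray
    theta2: np.ndarray
    delta: float
    indirect: np.ndarray                # theta1 * theta2 per mediator
    reverse: bool
    instrument_snps: list[str]
    own_snps: list[list[str]]


@dataclass
class Cohort:
    """One simulated population with GWAS role assignments."""

    config: ScenarioConfig
    snp_meta: pd.DataFrame = field(repr=False)
    genotypes: np.ndarray = field(repr=False)
    exposure: np.ndarray = field(repr=False)
    mediators: np.ndarray = field(repr=False)      # (N, K)
    outcome: np.ndarray = field(repr=False)
    roles: dict[str, slice] = field(repr=False)
    truth: CohortTruth = field(repr=False)

    @property
    def mediator_names(self) -> list[str]:
        return [m.name for m in self.config.mediator_specs()]

    def _phenotype(self, trait: str) -> tuple[np.ndarray, str]:
        if trait == "exposure":
            return self.exposure, "continuous"
        if trait == "outcome":
            return self.outcome.astype(float), "binary"
        try:
            k = self.mediator_names.index(trait)
        except ValueError:
            raise KeyError(f"unknown trait {trait!r}") from None
        return self.mediators[:, k], "continuous"

    def gwas(self, trait: str, role: str | None = None, trait_id: str | None = None) -> SummaryStatTable:
        """Summary statistics for ``trait`` in its (or the given) role cohort."""
        if role is None:
            role = trait if trait in ("exposure", "outcome") else "mediator"
        idx = self.roles[role]
        y, trait_type = self._phenotype(trait)
        return summary_stats_from_cohort(
            self.genotypes[idx], y[idx], trait_type, self.snp_meta,
            trait_id=trait_id or trait,
        )

    def genotype_matrix(self, snp_ids: list[str], role: str) -> np.ndarray:
        cols = [self.snp_meta.index.get_loc(s) for s in snp_ids]
        return self.genotypes[self.roles[role]][:, cols].astype(float)

    def ld_matrix(self, snp_ids: list[str] | None = None) -> LDMatrix:
        """Empirical pairwise r-squared in the exposure-role cohort."""
        if snp_ids is None:
            snp_ids = list(self.snp_meta.index)
        g = self.genotype_matrix(snp_ids, "exposure")
        r = np.corrcoef(g, rowvar=False)
        r = np.atleast_2d(r)
        np.fill_diagonal(r, 1.0)
        return LDMatrix(snps=list(snp_ids), r2=np.clip(r**2, 0.0, 1.0))


def _bernoulli_corr(rho: float, p: float) -> float:
    """Correlation of two Bernoulli(p) from thresholded equicorrelated normals."""
    z = stats.norm.ppf(p)
    p11 = stats.multivariate_normal.cdf([z, z], mean=[0, 0], cov=[[1, rho], [rho, 1]])
    return (p11 - p * p) / (p * (1 - p))


def _calibrate_copula_rho(target_r: float, maf: float) -> float:
    """Latent correlation giving genotype correlation ``target_r``."""
    if target_r <= 0:
        return 0.0
    f = lambda rho: _bernoulli_corr(rho, maf) - target_r
    hi = 0.999
    if f(hi) < 0:
        return hi
    return float(brentq(f, 0.0, hi, xtol=1e-4))


def _draw_genotypes(rng, mafs: np.ndarray, n: int, ld_blocks, block_of: np.ndarray) -> np.ndarray:
    """Binomial(2, maf) dosages, optionally block-correlated via a Gaussian copula.

    Haplotypes within an LD block come from thresholded equicorrelated
    latent normals; the latent correlation is calibrated so that the
    realized dosage r-squared matches the requested within-block value.
    """
    j = len(mafs)
    if ld_blocks is None:
        return rng.binomial(2, mafs[None, :], size=(n, j)).astype(np.int8)
    _, target_r2 = ld_blocks
    target_r = float(np.sqrt(target_r2))
    g = np.empty((n, j), dtype=np.int8)
    for bid in np.unique(block_of):
        cols = np.where(block_of == bid)[0]
        maf = float(mafs[cols[0]])  # one maf per block keeps calibration exact
        if len(cols) == 1 or target_r == 0.0:
            g[:, cols] = rng.binomial(2, maf, size=(n, len(cols)))
            continue
        rho = _calibrate_copula_rho(target_r, maf)
        zc = stats.norm.ppf(maf)
        dose = np.zeros((n, len(cols)), dtype=np.int8)
        for _hap in range(2):
            common = rng.standard_normal((n, 1))
            z = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal((n, len(cols)))
            dose += (z < zc).astype(np.int8)
        g[:, cols] = dose
    return g


def _scaled_effects(rng, mafs: np.ndarray, h2: float) -> np.ndarray:
    """Per-SNP additive effects scaled so the block explains ``h2`` variance.

    Magnitudes are uniform on (0.5, 1.5) before scaling — a moderate spread
    of instrument strengths — and positive: effect-allele coding is
    arbitrary, so orienting all effects trait-increasing loses no
    generality while making directional pleiotropy meaningful.
    """
    j = len(mafs)
    if h2 == 0 or j == 0:
        return np.zeros(j)
    raw = rng.uniform(0.5, 1.5, size=j)
    var = np.sum(raw**2 * 2 * mafs * (1 - mafs))
    return raw * np.sqrt(h2 / var)


def simulate_cohort(config: ScenarioConfig) -> Cohort:
    """Simulate genotypes and phenotypes for one seeded scenario.

    Returns a :class:`Cohort` with disjoint (by default) exposure,
    mediator and outcome GWAS sub-cohorts and the realized ground truth.
    Raises :class:`ScenarioError` when the requested variance components
    are infeasible (negative residual variance).
    """
    specs = config.mediator_specs()
    k = len(specs)
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
    rng_meta, rng_geno, rng_eff, rng_noise, rng_out = rngs

    n = config.n_per_cohort
    shift = int(round(n * (1.0 - config.overlap_frac)))
    starts = [0, shift, 2 * shift]
    total = starts[2] + n
    roles = {
        "exposure": slice(starts[0], starts[0] + n),
        "mediator": slice(starts[1], starts[1] + n),
        "outcome": slice(starts[2], starts[2] + n),
    }

    # --- SNP metadata ---------------------------------------------------
    j0 = config.n_snps
    n_own = [m.n_own_snps for m in specs]
    j_total = j0 + sum(n_own)
    if config.ld_blocks is not None:
        block_size = max(1, int(config.ld_blocks[0]))
        block_of = np.arange(j_total) // block_size
    else:
        block_of = np.arange(j_total)
    mafs = np.empty(j_total)
    for bid in np.unique(block_of):
        cols = np.where(block_of == bid)[0]
        mafs[cols] = rng_meta.uniform(*config.maf_range)
    pair_idx = rng_meta.integers(0, len(_ALLELE_PAIRS), size=j_total)
    snp_ids = [f"rs{i + 1}" for i in range(j_total)]
    # one block per "locus": same chromosome, nearby positions; distinct
    # loci are placed far apart so only true LD partners fall in a clump window
    chroms, positions = [], []
    for i in range(j_total):
        locus = int(block_of[i])
        within = int(i - np.argmax(block_of == block_of[i]))
        chroms.append(str(locus % 22 + 1))
        positions.append(50_000_000 * (locus // 22 + 1) + 10_000 * within + 1)
    snp_meta = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": chroms,
            "pos": positions,
            "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
            "maf": mafs,
        }
    ).set_index("snp", drop=False)

    genotypes = _draw_genotypes(rng_geno, mafs, total, config.ld_blocks, block_of)
    g = genotypes.astype(np.float64)

    # --- effect draws ---------------------------------------------------
    inst_cols = np.arange(j0)
    own_cols: list[np.ndarray] = []
    off = j0
    for m in range(k):
        own_cols.append(np.arange(off, off + n_own[m]))
        off += n_own[m]

    a = _scaled_effects(rng_eff, mafs[inst_cols], config.exposure_h2)
    b_list, gamma_list, gy_list = [], [], []
    for spec in specs:
        b_list.append(_scaled_effects(rng_eff, mafs[own_cols[len(b_list)]], spec.own_h2))
        gam = np.zeros(j0)
        if spec.pleiotropy != "none" and spec.pleiotropy_scale > 0:
            n_bad = int(np.ceil(spec.pleiotropy_frac * j0))
            bad = rng_eff.choice(j0, size=n_bad, replace=False)
            gam[bad] = spec.pleiotropy_scale
            if spec.pleiotropy == "balanced":
                gam[bad] *= rng_eff.choice([-1.0, 1.0], size=n_bad)
            elif spec.pleiotropy != "directional":
                raise ScenarioError(f"unknown pleiotropy mode {spec.pleiotropy!r}")
        gamma_list.append(gam)
        gy = np.zeros(len(own_cols[len(gy_list)]))
        if spec.het_scale > 0:
            gy = rng_eff.normal(0.0, spec.het_scale, size=len(gy))
        gy_list.append(gy)

    theta1 = np.array([m.theta1 for m in specs])
    theta2 = np.array([m.theta2 for m in specs])

    # --- phenotypes -----------------------------------------------------
    tpq = 2 * mafs * (1 - mafs)
    g_inst = g[:, inst_cols]
    if config.reverse:
        # instruments act on the (single) mediator; exposure is downstream
        if k != 1:
            raise ScenarioError("reverse scenarios support exactly one mediator")
        spec = specs[0]
        var_m_resid = 1.0 - config.exposure_h2 - spec.own_h2
        if var_m_resid <= 0:
            raise ScenarioError("infeasible: mediator residual variance <= 0")
        med = (
            g_inst @ a
            + g[:, own_cols[0]] @ b_list[0]
            + rng_noise.normal(0, np.sqrt(var_m_resid), total)
        )
        var_x_resid = 1.0 - theta1[0] ** 2
        if var_x_resid <= 0:
            raise ScenarioError("infeasible: exposure residual variance <= 0")
        exposure = theta1[0] * med + rng_noise.normal(0, np.sqrt(var_x_resid), total)
        mediators = med[:, None]
    else:
        var_x_resid = 1.0 - config.exposure_h2
        exposure = g_inst @ a + rng_noise.normal(0, np.sqrt(var_x_resid), total)
        mediators = np.empty((total, k))
        for m, spec in enumerate(specs):
            var_pleio = float(np.sum(gamma_list[m] ** 2 * tpq[inst_cols]))
            var_resid = 1.0 - spec.theta1**2 - spec.own_h2 - var_pleio
            if var_resid <= 0:
                raise ScenarioError(
                    f"infeasible mediator {spec.name!r}: theta1^2 + own_h2 + pleiotropy "
                    f"variance = {1.0 - var_resid:.3f} >= 1"
                )
            mediators[:, m] = (
                spec.theta1 * exposure
                + g[:, own_cols[m]] @ b_list[m]
                + g_inst @ gamma_list[m]
                + rng_noise.normal(0, np.sqrt(var_resid), total)
            )

    eta = config.delta_direct * exposure + mediators @ theta2
    for m in range(k):
        if gy_list[m].any():
            eta = eta + g[:, own_cols[m]] @ gy_list[m]

    prev = config.outcome_prevalence
    if config.liability_link == "logistic":
        c = brentq(lambda c0: float(np.mean(expit(c0 + eta))) - prev,
                   logit(prev) - 30, logit(prev) + 30)
        outcome = (rng_out.random(total) < expit(c + eta)).astype(np.int8)
    else:
        liab = eta + rng_out.standard_normal(total)
        thr = np.quantile(liab, 1.0 - prev)
        outcome = (liab > thr).astype(np.int8)

    truth = CohortTruth(
        a=a, b=b_list, gamma=gamma_list, gamma_y=gy_list,
        theta1=theta1, theta2=theta2, delta=config.delta_direct,
        indirect=theta1 * theta2, reverse=config.reverse,
        instrument_snps=[snp_ids[i] for i in inst_cols],
        own_snps=[[snp_ids[i] for i in cols] for cols in own_cols],
    )
    return Cohort(
        config=config, snp_meta=snp_meta, genotypes=genotypes,
        exposure=exposure, mediators=mediators, outcome=outcome,
        roles=roles, truth=truth,
    )


# --- summary statistics ------------------------------------------------


def _ols_per_snp(g: np.ndarray, y: np.ndarray):
    """Vectorized simple linear regression of y on each SNP dosage."""
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(gc**2, axis=0)
    mono = sxx == 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = gc.T @ yc / sxx_safe
    syy = float(np.sum(yc**2))
    rss = syy - beta**2 * sxx_safe
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx_safe)
    se_safe = np.where(se == 0, np.nan, se)
    tstat = beta / se_safe
    pval = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    pval = np.where(np.isnan(pval), 1.0, pval)
    return beta, se, pval, mono


def _logistic_per_snp(g: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-8):
    """Vectorized per-SNP logistic regression (intercept + dosage).

    One Newton-Raphson solve per SNP, run simultaneously across SNPs; the
    2x2 information matrix is inverted in closed form.
    """
    n, j = g.shape
    ybar = float(np.mean(y))
    alpha = np.full(j, logit(min(max(ybar, 1e-10), 1 - 1e-10)))
    beta = np.zeros(j)
    mono = g.var(axis=0) == 0
    yv = y.astype(float)
    for _ in range(max_iter):
        eta = alpha[None, :] + beta[None, :] * g
        p = expit(eta)
        w = p * (1 - p)
        resid = yv[:, None] - p
        u1 = resid.sum(axis=0)
        u2 = (resid * g).sum(axis=0)
        h11 = w.sum(axis=0)
        h12 = (w * g).sum(axis=0)
        h22 = (w * g * g).sum(axis=0)
        det = np.maximum(h11 * h22 - h12**2, 1e-300)
        da = (h22 * u1 - h12 * u2) / det
        db = (h11 * u2 - h12 * u1) / det
        da[mono] = 0.0
        db[mono] = 0.0
        alpha += da
        beta += db
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
            break
    se = np.sqrt(h11 / det)
    se_safe = np.where(se == 0, np.nan, se)
    z = beta / se_safe
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.where(np.isnan(pval), 1.0, pval)
    return beta, se, pval, mono


def summary_stats_from_cohort(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    trait_type: str,
    snp_meta: pd.DataFrame,
    trait_id: str = "trait",
) -> SummaryStatTable:
    """Per-SNP association scan of one cohort.

    Continuous traits use simple OLS per SNP; binary traits a per-SNP
    logistic fit (beta on the log-odds scale).  Monomorphic SNPs are
    emitted with eaf 0/1, beta 0 and an uninformative SE, and flagged in
    the log.
    """
    g = genotypes.astype(np.float64)
    y = np.asarray(phenotype, dtype=float)
    if g.shape[0] != len(y):
        raise ValueError("phenotype length does not match genotype rows")
    if trait_type == "continuous":
        beta, se, pval, mono = _ols_per_snp(g, y)
    elif trait_type == "binary":
        beta, se, pval, mono = _logistic_per_snp(g, y)
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")
    if mono.any():
        logger.warning("summary_stats_from_cohort: %d monomorphic SNP(s) flagged", int(mono.sum()))
        beta = np.where(mono, 0.0, beta)
        se = np.where(mono, 1e6, se)
        pval = np.where(mono, 1.0, pval)
    eaf = g.mean(axis=0) / 2.0
    df = pd.DataFrame(
        {
            "snp": snp_meta["snp"].to_numpy(),
            "chrom": snp_meta["chrom"].to_numpy(),
            "pos": snp_meta["pos"].to_numpy(),
            "effect_allele": snp_meta["effect_allele"].to_numpy(),
            "other_allele": snp_meta["other_allele"].to_numpy(),
            "eaf": eaf,
            "beta": beta,
            "se": np.where(se <= 0, 1e6, se),
            "pval": np.clip(pval, np.nextafter(0, 1), 1.0),
            "n": float(len(y)),
        },
        columns=CANONICAL_COLUMNS,
    )
    return SummaryStatTable(trait_id=trait_id, trait_type=trait_type, records=df)


@dataclass
class TSLSResult:
    beta: float
    se: float
    pval: float
    stage1_r2: float   # the screening tables' "multiple R-squared"
    n: int


def two_stage_least_squares(
    genotypes: np.ndarray, exposure: np.ndarray, response: np.ndarray
) -> TSLSResult:
    """Two-stage least squares with SNP dosages as instruments.

    Stage 1 regresses the exposure on all instruments; stage 2 regresses
    the response on the fitted exposure.  The residual variance for the
    coefficient SE uses the *actual* exposure (the proper 2SLS variance).
    Binary responses are handled as a linear-probability stage 2 with a
    logged caveat.
    """
    g = np.asarray(genotypes, dtype=float)
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(response, dtype=float)
    n = len(x)
    if set(np.unique(y)) <= {0.0, 1.0}:
        logger.warning("two_stage_least_squares: binary response, linear-probability stage 2")
    z = np.column_stack([np.ones(n), g])
    coef1, _, rank, _ = np.linalg.lstsq(z, x, rcond=None)
    if rank < z.shape[1]:
        raise ScenarioError("rank-deficient stage-1 design (collinear instruments)")
    xhat = z @ coef1
    tss = float(np.sum((x - x.mean()) ** 2))
    stage1_r2 = 1.0 - float(np.sum((x - xhat) ** 2)) / tss if tss > 0 else 0.0
    x2 = np.column_stack([np.ones(n), xhat])
    xtx = x2.T @ x2
    coef2 = np.linalg.solve(xtx, x2.T @ y)
    resid = y - coef2[0] - coef2[1] * x  # actual exposure in the residual
    sigma2 = float(resid @ resid) / (n - 2)
    cov = sigma2 * np.linalg.inv(xtx)
    se = float(np.sqrt(cov[1, 1]))
    tstat = coef2[1] / se
    pval = float(2.0 * stats.t.sf(abs(tstat), n - 2))
    return TSLSResult(beta=float(coef2[1]), se=se, pval=pval, stage1_r2=stage1_r2, n=n)


# --- named presets ------------------------------------------------------

_PRESETS: dict[str, dict] = {
    "null": dict(theta1=0.0, theta2=0.0, delta_direct=0.0),
    "mediated": dict(theta1=0.4, theta2=0.5, delta_direct=0.0),
    "direct_only": dict(theta1=0.0, theta2=0.0, delta_direct=0.3),
    "pleiotropic": dict(
        theta1=0.4, theta2=0.5, delta_direct=0.0,
        pleiotropy="directional", pleiotropy_frac=0.3, pleiotropy_scale=0.04,
    ),
    "heterogeneous": dict(theta1=0.4, theta2=0.5, delta_direct=0.0, het_scale=0.15),
    "reverse": dict(theta1=0.5, theta2=0.0, delta_direct=0.0, reverse=True, exposure_h2=0.3),
}


def build_scenario(name: str, **overrides) -> ScenarioConfig:
    """Return the fully seeded configuration of a named scenario preset.

    Presets: ``null`` (no causal links), ``mediated`` (theta1=0.4,
    theta2=0.5, indirect 0.2), ``direct_only``, ``pleiotropic`` (30% of
    instruments with directional direct effects), ``heterogeneous``
    (dispersed mediator-SNP effects on the outcome) and ``reverse``
    (instruments act on the mediator; the exposure is downstream).
    """
    if name not in _PRESETS:
        raise ScenarioError(f"unknown scenario {name!r}; valid: {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return ScenarioConfig(**params)


#: fixed seed of the packaged screening fixture; part of the fixture
#: definition, so the designed truth is reproduced exactly on every run
SCREENING_FIXTURE_SEED = 730062


def screening_fixture(n_per_cohort: int = 20_000) -> Cohort:
    """The packaged 10-mediator screening fixture (deterministic).

    Designed truth: three genuine mediators, two mediators whose
    step-1 run is contaminated by directional pleiotropy, two whose
    step-2 run is heterogeneous, and three nulls.  The two-step screen
    should recover exactly the three genuine mediators.
    """
    specs = [
        MediatorSpec("region_a:true1", theta1=0.40, theta2=0.50),
        MediatorSpec("region_a:true2", theta1=0.35, theta2=0.50),
        MediatorSpec("region_b:true3", theta1=0.45, theta2=0.45),
        # pure horizontal pleiotropy: the exposure's instruments reach these
        # traits only directly (constant per-SNP effect), so the step-1
        # association is spurious and the Egger intercept estimand is
        # exactly the per-SNP direct effect
        MediatorSpec("region_b:pleio1", theta1=0.0, theta2=0.0,
                     pleiotropy="directional", pleiotropy_frac=1.0,
                     pleiotropy_scale=0.05),
        MediatorSpec("region_c:pleio2", theta1=0.0, theta2=0.0,
                     pleiotropy="directional", pleiotropy_frac=1.0,
                     pleiotropy_scale=0.05),
        MediatorSpec("region_c:het1", theta1=0.40, theta2=0.50, het_scale=0.15),
        MediatorSpec("region_d:het2", theta1=0.40, theta2=0.50, het_scale=0.15),
        MediatorSpec("region_d:null1"),
        MediatorSpec("region_e:null2"),
        MediatorSpec("region_e:null3"),
    ]
    config = ScenarioConfig(
        n_per_cohort=n_per_cohort, mediators=specs, seed=SCREENING_FIXTURE_SEED
    )
    return simulate_cohort(config)


def truth_manifest(cohort: Cohort) -> dict:
    """JSON-serializable record of the scenario's true parameters."""
    t = cohort.truth
    cfg = asdict(cohort.config)
    cfg["mediators"] = [asdict(m) for m in cohort.config.mediator_specs()]
    return {
        "config": cfg,
        "theta1": t.theta1.tolist(),
        "theta2": t.theta2.tolist(),
        "delta_direct": t.delta,
        "indirect": t.indirect.tolist(),
        "reverse": t.reverse,
        "instrument_snps": t.instrument_snps,
        "instrument_effects": t.a.tolist(),
        "own_snps": t.own_snps,
    }
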