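"""Instrumental-variable selection for summary-statistic MR.

A valid instrument must be (i) genome-wide associated with the exposure,
(ii) approximately independent of other instruments (LD clumping), (iii)
not directly associated with the outcome or a listed confounder trait, and
(iv) strong, measured by the per-SNP F-statistic

    F = R^2 (N - K - 1) / (K (1 - R^2)),   K = 1 per SNP,

with R^2 approximated from the per-SNP t-statistic as t^2 / (t^2 + n - 2).
Instruments with F > 10 are conventionally retained.

All selection operations are subset operations on an instrument table (the
exposure's canonical summary-stat columns plus ``r2_snp`` and ``f_stat``),
preserving input order unless stated otherwise, and logging drop counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas_io import GwasIOError, SummaryStatTable, logger


@dataclass
class LDMatrix:
    """Pairwise r-squared between SNPs (symmetric, unit diagonal)."""

    snps: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        j = len(self.snps)
        if self.r2.shape != (j, j):
            raise ValueError(f"LD matrix shape {self.r2.shape} != ({j}, {j})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal must be 1")
        if (self.r2 < -1e-9).any() or (self.r2 > 1 + 1e-9).any():
            raise ValueError("LD r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snps)}

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def pair(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def read(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(snps=[str(c) for c in df.columns], r2=df.to_numpy(dtype=float))

    def write(self, path) -> None:
        pd.DataFrame(self.r2, columns=self.snps).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def _instrument_frame(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    for col in ("r2_snp", "f_stat"):
        if col not in df.columns:
            df[col] = np.nan
    return df


def select_genomewide(exposure: SummaryStatTable, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Retain records with exposure p strictly below ``p_threshold``."""
    df = _instrument_frame(exposure.records)
    out = df.loc[df["pval"] < p_threshold].reset_index(drop=True)
    if out.empty:
        logger.warning(
            "no instruments reach p < %g for %s", p_threshold, exposure.trait_id
        )
    return out


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDMatrix,
    positions: dict[str, tuple[str, int]] | None = None,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> pd.DataFrame:
    """Greedy LD clumping.

    Candidates are visited in ascending exposure p-value (ties broken by
    position, then SNP id); a SNP is accepted iff every already-accepted
    SNP on the same chromosome within ``window_kb`` has pairwise r-squared
    below ``r2_threshold`` with it.  SNPs on different chromosomes or
    beyond the window never conflict.  The result is ordered by
    (chromosome, position).  SNPs absent from the LD matrix are dropped
    with a warning.
    """
    if positions is None:
        positions = {
            r.snp: (str(r.chrom), int(r.pos)) for r in candidates.itertuples()
        }
    in_ld = candidates["snp"].map(lambda s: s in ld)
    n_missing = int((~in_ld).sum())
    if n_missing:
        logger.warning("ld_clump: %d candidate(s) absent from LD matrix, dropped", n_missing)
    df = candidates.loc[in_ld]
    order = df.assign(
        _pos=[positions[s][1] for s in df["snp"]],
    ).sort_values(["pval", "_pos", "snp"], kind="mergesort")
    accepted: list[str] = []
    window_bp = window_kb * 1000
    for row in order.itertuples():
        chrom, pos = positions[row.snp]
        conflict = False
        for kept in accepted:
            kc, kp = positions[kept]
            if kc == chrom and abs(kp - pos) <= window_bp:
                if ld.pair(row.snp, kept) >= r2_threshold:
                    conflict = True
                    break
        if not conflict:
            accepted.append(row.snp)
    keep = candidates["snp"].isin(accepted)
    out = candidates.loc[keep]
    out = out.assign(
        _chrom=[positions[s][0] for s in out["snp"]],
        _pos=[positions[s][1] for s in out["snp"]],
    ).sort_values(["_chrom", "_pos"], kind="mergesort").drop(columns=["_chrom", "_pos"])
    logger.info("ld_clump: %d -> %d instruments", len(candidates), len(out))
    return out.reset_index(drop=True)


def exclude_outcome_associated(
    instruments: pd.DataFrame,
    outcome: SummaryStatTable,
    p_threshold: float = 5e-8,
) -> pd.DataFrame:
    """Drop instruments significantly associated with the outcome itself.

    Instruments missing from the outcome table are retained (no evidence
    of association) with a log note.
    """
    out_p = outcome.records.set_index("snp")["pval"]
    p = instruments["snp"].map(out_p)
    n_absent = int(p.isna().sum())
    if n_absent:
        logger.info(
            "exclude_outcome_associated: %d instrument(s) absent from outcome table, retained",
            n_absent,
        )
    drop = p.notna() & (p < p_threshold)
    if drop.any():
        logger.info(
            "exclude_outcome_associated: dropped %d instrument(s) with outcome p < %g",
            int(drop.sum()), p_threshold,
        )
    return instruments.loc[~drop].reset_index(drop=True)


def exclude_listed_confounders(
    instruments: pd.DataFrame,
    lookup: pd.DataFrame | None,
    confounder_traits: list[str],
) -> pd.DataFrame:
    """Drop instruments linked to a confounder trait in an offline lookup.

    ``lookup`` has columns ``snp_id`` and ``trait``; matching is
    case-insensitive substring (lookup trait contains a listed confounder
    term, or vice versa).  This replaces live LDlink / GWAS-Catalog
    queries with a local table.
    """
    if lookup is None or len(lookup) == 0 or not confounder_traits:
        return instruments.reset_index(drop=True)
    terms = [t.lower() for t in confounder_traits]
    bad: set[str] = set()
    for row in lookup.itertuples():
        trait = str(row.trait).lower()
        if any(term in trait or trait in term for term in terms):
            bad.add(str(row.snp_id))
    drop = instruments["snp"].isin(bad)
    if drop.any():
        logger.info(
            "exclude_listed_confounders: dropped %d instrument(s) linked to %s",
            int(drop.sum()), confounder_traits,
        )
    return instruments.loc[~drop].reset_index(drop=True)


def compute_f_statistics(
    instruments: pd.DataFrame, n_override: int | None = None
) -> pd.DataFrame:
    """Fill ``r2_snp`` and ``f_stat`` per instrument.

    R^2 per SNP defaults to t^2/(t^2 + n - 2) with t = beta/se (the
    standard summary-data approximation); rows with a pre-supplied
    ``r2_snp`` keep it.  F = R^2 (N - 2) / (1 - R^2) for K = 1.
    """
    df = instruments.copy()
    n = np.full(len(df), float(n_override)) if n_override is not None else df["n"].to_numpy(float)
    if np.any(n <= 2):
        bad = df.loc[n <= 2, "snp"].tolist()
        raise ValueError(f"sample size must exceed K+1=2 to compute F: {bad[:5]}")
    t2 = (df["beta"].to_numpy(float) / df["se"].to_numpy(float)) ** 2
    r2_default = t2 / (t2 + n - 2)
    r2 = df["r2_snp"].to_numpy(float)
    r2 = np.where(np.isnan(r2), r2_default, r2)
    f = r2 * (n - 2) / (1.0 - r2)
    df["r2_snp"] = r2
    df["f_stat"] = f
    return df


def filter_weak_instruments(instruments: pd.DataFrame, f_min: float = 10.0) -> pd.DataFrame:
    """Retain instruments with F strictly greater than ``f_min``."""
    if instruments["f_stat"].isna().any():
        raise ValueError("f_stat not populated; run compute_f_statistics first")
    out = instruments.loc[instruments["f_stat"] > f_min].reset_index(drop=True)
    n_drop = len(instruments) - len(out)
    if n_drop:
        logger.info("filter_weak_instruments: dropped %d instrument(s) with F <= %g", n_drop, f_min)
    if out.empty:
        logger.warning("filter_weak_instruments: no instruments remain")
    return out
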