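"""Reading, validation and harmonization of GWAS summary statistics.

The unit of data is a :class:`SummaryStatTable`: one trait's per-SNP
association records (identifier, coordinates, alleles, effect-allele
frequency, beta, SE, p-value, sample size).  Effect sizes for binary traits
are on the log-odds scale.  Harmonization joins an exposure table with an
outcome table on SNP identifier and aligns both to the exposure's effect
allele, resolving strand flips and (optionally) palindromic variants by
allele frequency.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrmediate")
if not logger.handlers:  # default: counts of dropped/flipped SNPs to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: canonical column order for summary-statistic tables
CANONICAL_COLUMNS = [
    "snp", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: columns of a harmonized exposure/outcome record set
HARMONIZED_COLUMNS = [
    "snp",
    "beta_exp", "se_exp", "pval_exp", "n_exp",
    "beta_out", "se_out", "pval_out", "n_out",
    "eaf", "flipped", "palindromic",
]


class GwasIOError(RuntimeError):
    """Fatal input problem (unreadable file, missing column, empty join)."""


@dataclass
class SummaryStatTable:
    """Per-SNP association records for one trait.

    ``records`` holds the canonical columns; ``snp`` is unique within a
    table.  ``trait_type`` is ``"continuous"`` or ``"binary"`` (binary betas
    are log odds ratios).
    """

    trait_id: str
    trait_type: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous/binary, got {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing canonical columns: {missing}")
        if self.records["snp"].duplicated().any():
            dups = self.records.loc[self.records["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate snp ids in table {self.trait_id!r}: {dups[:5]}")
        self.records = self.records.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.records)


def _validate_records(df: pd.DataFrame, trait_id: str) -> pd.DataFrame:
    """Drop rows violating hard invariants; warn on soft inconsistencies.

    Hard invariants: alleles single A/C/G/T and distinct; se > 0; pval in
    (0, 1]; n > 0; eaf in [0, 1] when present.  A p-value inconsistent with
    |beta/se| by more than two-fold (on the -log10 scale of the implied
    normal p) only triggers a warning: rounding in public GWAS files breaks
    exact agreement.
    """
    df = df.copy()
    ok = pd.Series(True, index=df.index)
    ok &= df["effect_allele"].isin(_VALID_ALLELES) & df["other_allele"].isin(_VALID_ALLELES)
    ok &= df["effect_allele"] != df["other_allele"]
    ok &= df["se"] > 0
    ok &= (df["pval"] > 0) & (df["pval"] <= 1)
    ok &= df["n"] > 0
    eaf_ok = df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))
    ok &= eaf_ok
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("table %s: dropped %d record(s) failing validation", trait_id, n_dropped)
    df = df.loc[ok].reset_index(drop=True)

    with np.errstate(divide="ignore"):
        z = np.abs(df["beta"].to_numpy() / df["se"].to_numpy())
        implied = 2.0 * stats.norm.sf(z)
    both = (implied > 0) & (df["pval"].to_numpy() > 0)
    ratio = np.ones(len(df))
    ratio[both] = np.log(np.maximum(df["pval"].to_numpy()[both], 1e-300)) / np.log(
        np.maximum(implied[both], 1e-300)
    )
    n_soft = int(np.sum(both & ((ratio > 2) | (ratio < 0.5)) & (implied < 0.5)))
    if n_soft:
        logger.warning(
            "table %s: %d record(s) have pval inconsistent with |beta/se| (>2-fold); kept",
            trait_id, n_soft,
        )
    return df


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    trait_type: str = "continuous",
    trait_id: str | None = None,
) -> SummaryStatTable:
    """Read a tab- or comma-delimited summary-statistic file.

    ``column_map`` maps canonical field names (``snp``, ``beta`` ...) to the
    source file's header names; fields absent from the map are looked up
    under their canonical name.  Rows failing hard invariants are dropped
    and counted in the log.  Missing ``eaf`` is preserved as NaN.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise GwasIOError(f"cannot read summary statistics from {path}: {exc}") from exc
    column_map = column_map or {}
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in df.columns:
            if canon == "eaf" and canon not in column_map:
                df["eaf"] = np.nan
                continue
            raise GwasIOError(f"required column {canon!r} (source header {src!r}) absent in {path}")
        rename[src] = canon
    df = df.rename(columns=rename)[CANONICAL_COLUMNS]
    df["snp"] = df["snp"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    for a in ("effect_allele", "other_allele"):
        df[a] = df[a].astype(str).str.upper()
    for c in ("eaf", "beta", "se", "pval", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    tid = trait_id if trait_id is not None else str(path)
    df = _validate_records(df, tid)
    return SummaryStatTable(trait_id=tid, trait_type=trait_type, records=df)


def write_summary_stats(table: SummaryStatTable, path) -> None:
    """Write the canonical tab-delimited layout (read∘write is identity)."""
    try:
        table.records.to_csv(path, sep="\t", index=False, float_format="%.10g")
    except OSError as exc:
        raise GwasIOError(f"cannot write summary statistics to {path}: {exc}") from exc


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize_pair(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    palindromic_policy: str = "drop",
    eaf_window: float = 0.08,
) -> pd.DataFrame:
    """Join exposure and outcome records on SNP and align effect alleles.

    Alignment logic per shared SNP, relative to the exposure's
    (effect, other) allele pair:

    * same pair -> keep outcome as is;
    * swapped pair -> negate ``beta_out``, ``eaf_out <- 1 - eaf_out``;
    * complementary-strand pair -> complement, then apply the same logic;
    * palindromic (A/T or C/G) -> per ``palindromic_policy``: ``"drop"``,
      or ``"infer_by_eaf"`` which orients by allele frequency when both
      sides' eaf lie outside ``[0.5 - eaf_window, 0.5 + eaf_window]``
      (else dropped; missing eaf always dropped);
    * anything else is irreconcilable and dropped with a log entry.

    Returns a DataFrame with :data:`HARMONIZED_COLUMNS`; ``eaf`` is the
    exposure-side effect-allele frequency.
    """
    if palindromic_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindromic_policy {palindromic_policy!r}")
    exp = exposure.records.set_index("snp")
    out = outcome.records.set_index("snp")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise GwasIOError(
            f"no shared SNPs between {exposure.trait_id!r} and {outcome.trait_id!r}"
        )
    rows = []
    n_flipped = n_palin_dropped = n_irrec = 0
    for snp in shared:
        e = exp.loc[snp]
        o = out.loc[snp]
        ea, oa = e["effect_allele"], e["other_allele"]
        ea2, oa2 = o["effect_allele"], o["other_allele"]
        beta_out, eaf_out = float(o["beta"]), float(o["eaf"])
        palindromic = _is_palindromic(ea, oa)

        if palindromic:
            if {ea2, oa2} != {ea, oa}:
                n_irrec += 1
                continue
            if palindromic_policy == "drop":
                n_palin_dropped += 1
                continue
            eaf_e = float(e["eaf"])
            if (
                np.isnan(eaf_e) or np.isnan(eaf_out)
                or abs(eaf_e - 0.5) <= eaf_window
                or abs(eaf_out - 0.5) <= eaf_window
            ):
                n_palin_dropped += 1
                continue
            # orient so minor/major status agrees across studies
            flipped = (eaf_e - 0.5) * (eaf_out - 0.5) < 0
            if flipped:
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                n_flipped += 1
        else:
            if (ea2, oa2) == (ea, oa):
                flipped = False
            elif (ea2, oa2) == (oa, ea):
                flipped = True
            elif (ea2, oa2) == (_COMPLEMENT[ea], _COMPLEMENT[oa]):
                flipped = False
            elif (ea2, oa2) == (_COMPLEMENT[oa], _COMPLEMENT[ea]):
                flipped = True
            else:
                n_irrec += 1
                continue
            if flipped:
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                n_flipped += 1

        rows.append(
            dict(
                snp=snp,
                beta_exp=float(e["beta"]), se_exp=float(e["se"]),
                pval_exp=float(e["pval"]), n_exp=float(e["n"]),
                beta_out=beta_out, se_out=float(o["se"]),
                pval_out=float(o["pval"]), n_out=float(o["n"]),
                eaf=float(e["eaf"]),
                flipped=bool(flipped), palindromic=bool(palindromic),
            )
        )
    logger.info(
        "harmonize %s vs %s: %d shared, %d kept, %d flipped, %d palindromic dropped, "
        "%d irreconcilable",
        exposure.trait_id, outcome.trait_id,
        len(shared), len(rows), n_flipped, n_palin_dropped, n_irrec,
    )
    if not rows:
        return pd.DataFrame(columns=HARMONIZED_COLUMNS)
    return pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
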