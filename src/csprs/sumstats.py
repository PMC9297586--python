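"""GWAS summary-statistics I/O, effect standardization, allele harmonization, QC.

A polygenic-score run joins three variant sources: the GWAS summary
statistics, the LD reference panel, and the target cohort's variant list
(PLINK .bim).  Only SNPs present in all three, with mutually compatible
alleles, enter the model.  Marginal effects are put on the standardized
scale β̂ = sign(β) · z(p) / √n so that the Gibbs sampler can condition on
correlation (not covariance) matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError

__all__ = [
    "SumStatsRecord",
    "HarmonizedSumStats",
    "read_sumstats",
    "read_bim",
    "standardize_effects",
    "harmonize",
    "qc_filter",
    "COMPLEMENT",
]

# Smallest positive normal double is ~2.2e-308; 1e-323 is a subnormal that
# still yields a finite quantile (|z| ≈ 38.5).
P_FLOOR = 1e-323

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_ROLES = ("SNP", "A1", "A2", "BETA", "OR", "P", "SE")


@dataclass(frozen=True)
class SumStatsRecord:
    """One GWAS summary-statistics row; OR inputs are stored as log(OR)."""

    snp_id: str
    a1: str
    a2: str
    beta_raw: float
    p_value: float | None = None
    se: float | None = None

    def __post_init__(self):
        if self.a1 == self.a2:
            raise DataError(f"{self.snp_id}: effect and other allele are identical")


@dataclass
class HarmonizedSumStats:
    """Analysis-ready SNP set: reference orientation, standardized effects.

    ``table`` columns: snp_id, chrom, pos, a1, a2, beta_std, maf.
    ``n`` is the (global) GWAS sample size.
    """

    table: pd.DataFrame
    n: int

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def beta_std(self) -> np.ndarray:
        return self.table["beta_std"].to_numpy()


def _normalize_chrom(c) -> str:
    s = str(c).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def read_bim(path) -> pd.DataFrame:
    """Read a PLINK .bim variant list (6 columns, no header)."""
    try:
        bim = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
            dtype={"snp_id": str, "a1": str, "a2": str},
        )
    except (OSError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot read variant list {path}: {exc}") from exc
    if bim.shape[1] != 6 or len(bim) == 0:
        raise DataError(f"{path} is not a 6-column variant list")
    bim["chrom"] = bim["chrom"].map(_normalize_chrom)
    bim["a1"] = bim["a1"].str.upper()
    bim["a2"] = bim["a2"].str.upper()
    return bim


def read_sumstats(path, column_map: Mapping[str, str] | None = None) -> list[SumStatsRecord]:
    """Parse whitespace/tab-delimited summary statistics into records.

    ``column_map`` maps roles (SNP, A1, A2, BETA or OR, P, SE) to the column
    names actually present in the file; columns may appear in any order.
    Roles not in the map fall back to the role name itself, so files with
    canonical headers need no map at all.  OR effects are converted to
    log(OR).
    """
    column_map = dict(column_map or {})
    for role in column_map:
        if role not in _ROLES:
            raise ConfigurationError(f"unknown column role '{role}' (expected one of {_ROLES})")

    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise ConfigurationError(f"cannot read summary statistics {path}: {exc}") from exc

    def col(role: str) -> str | None:
        name = column_map.get(role, role)
        return name if name in df.columns else None

    snp_c, a1_c, a2_c = col("SNP"), col("A1"), col("A2")
    beta_c, or_c = col("BETA"), col("OR")
    p_c, se_c = col("P"), col("SE")

    for role, c in (("SNP", snp_c), ("A1", a1_c), ("A2", a2_c)):
        if c is None:
            raise ConfigurationError(
                f"summary statistics are missing a column for role {role} "
                f"(looked for '{column_map.get(role, role)}')"
            )
    if beta_c is None and or_c is None:
        raise ConfigurationError("summary statistics need a BETA or OR column")
    if p_c is None and se_c is None:
        raise ConfigurationError("summary statistics need a P or SE column")

    eff_c = beta_c if beta_c is not None else or_c
    eff = pd.to_numeric(df[eff_c], errors="coerce")
    bad = np.flatnonzero(eff.isna().to_numpy())
    if bad.size:
        # +2: header is line 1, data starts at line 2.
        raise DataError(f"non-numeric effect value at line {bad[0] + 2} of {path}")
    eff = eff.to_numpy(dtype=float)
    if or_c is not None and beta_c is None:
        if np.any(eff <= 0):
            line = int(np.flatnonzero(eff <= 0)[0]) + 2
            raise DataError(f"OR must be positive; offending line {line} of {path}")
        eff = np.log(eff)

    def numeric(c):
        if c is None:
            return None
        v = pd.to_numeric(df[c], errors="coerce")
        bad = np.flatnonzero(v.isna().to_numpy() & df[c].notna().to_numpy())
        if bad.size:
            raise DataError(f"non-numeric value in column {c} at line {bad[0] + 2} of {path}")
        return v.to_numpy(dtype=float)

    pvals = numeric(p_c)
    ses = numeric(se_c)
    if pvals is not None:
        if np.any((pvals < 0) | (pvals > 1) | np.isnan(pvals)):
            line = int(np.flatnonzero(~((pvals >= 0) & (pvals <= 1)))[0]) + 2
            raise DataError(f"P must lie in (0, 1]; offending line {line} of {path}")
        # Printed p-values can underflow double precision (e.g. 1e-400 -> 0);
        # floor instead of rejecting so the quantile transform stays finite.
        pvals = np.maximum(pvals, P_FLOOR)

    ids = df[snp_c].astype(str)
    dup = ids[ids.duplicated()].unique()
    if dup.size:
        raise DataError(f"duplicate SNP ids in {path}: {', '.join(dup[:10])}")

    a1 = df[a1_c].astype(str).str.upper().to_numpy()
    a2 = df[a2_c].astype(str).str.upper().to_numpy()
    return [
        SumStatsRecord(
            snp_id=ids.iloc[i],
            a1=a1[i],
            a2=a2[i],
            beta_raw=float(eff[i]),
            p_value=float(pvals[i]) if pvals is not None else None,
            se=float(ses[i]) if ses is not None else None,
        )
        for i in range(len(df))
    ]


def records_to_frame(records: Sequence[SumStatsRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "a1": [r.a1 for r in records],
            "a2": [r.a2 for r in records],
            "beta_raw": [r.beta_raw for r in records],
            "p_value": [r.p_value for r in records],
            "se": [r.se for r in records],
        }
    )


def standardize_effects(records: Sequence[SumStatsRecord] | pd.DataFrame, n: int,
                        mode: str = "p") -> np.ndarray:
    """Marginal effects on the standardized scale, β̂_std with Var ~ 1/n.

    mode "p" (default): β̂_std = sign(β) · z(p/2) / √n, with z the upper
    normal quantile; p-values below 1e-323 are floored so z stays finite.
    mode "se": β̂_std = (β / se) / √n.
    """
    if n <= 0:
        raise ConfigurationError("GWAS sample size n must be positive")
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    beta = df["beta_raw"].to_numpy(dtype=float)
    if mode == "p":
        p = df["p_value"].to_numpy(dtype=float)
        if np.any(np.isnan(p)):
            raise DataError("P-value standardization requested but P is missing for some rows")
        if np.any((p < 0) | (p > 1)):
            bad = df.loc[(p < 0) | (p > 1), "snp_id"].iloc[0]
            raise DataError(f"P outside (0, 1] for SNP {bad}")
        p = np.maximum(p, P_FLOOR)
        z = stats.norm.isf(p / 2.0)
        return np.sign(beta) * z / np.sqrt(n)
    if mode == "se":
        se = df["se"].to_numpy(dtype=float)
        if np.any(np.isnan(se)) or np.any(se <= 0):
            raise DataError("SE standardization requested but SE is missing or non-positive")
        return (beta / se) / np.sqrt(n)
    raise ConfigurationError(f"unknown standardization mode '{mode}' (use 'p' or 'se')")


def _match_alleles(s_a1, s_a2, r_a1, r_a2) -> int:
    """Allele configuration of sumstats (s) vs reference (r) coding.

    Returns +1 (same orientation), -1 (effect allele is the reference's A2,
    sign flips), or 0 (incompatible).  Non-complement configurations are
    tried first so palindromic A/T and C/G pairs resolve without a strand
    flip.
    """
    if s_a1 == r_a1 and s_a2 == r_a2:
        return 1
    if s_a1 == r_a2 and s_a2 == r_a1:
        return -1
    c1 = COMPLEMENT.get(s_a1)
    c2 = COMPLEMENT.get(s_a2)
    if c1 is None or c2 is None:
        return 0
    if c1 == r_a1 and c2 == r_a2:
        return 1
    if c1 == r_a2 and c2 == r_a1:
        return -1
    return 0


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def harmonize(
    records: Sequence[SumStatsRecord] | pd.DataFrame,
    ref_info: pd.DataFrame,
    bim: pd.DataFrame,
    n: int,
    mode: str = "p",
    drop_ambiguous: bool = False,
) -> HarmonizedSumStats:
    """Intersect sumstats with the LD reference and target variant list.

    Keeps SNPs present in all three sources whose alleles match the
    reference coding directly, swapped (β sign flips), strand-complemented,
    or both.  Output rows follow the reference's genomic order and allele
    orientation; ``ref_info`` needs columns CHR/SNP/BP/A1/A2/MAF.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.copy()
    df["beta_std"] = standardize_effects(df, n=n, mode=mode)
    if drop_ambiguous:
        pal = df.apply(lambda r: _is_palindromic(r["a1"], r["a2"]), axis=1)
        df = df.loc[~pal]

    ref = ref_info.rename(
        columns={"CHR": "chrom", "SNP": "snp_id", "BP": "pos", "A1": "ref_a1",
                 "A2": "ref_a2", "MAF": "maf"}
    ).copy()
    ref["chrom"] = ref["chrom"].map(_normalize_chrom)
    ref["ref_a1"] = ref["ref_a1"].str.upper()
    ref["ref_a2"] = ref["ref_a2"].str.upper()

    bim_min = bim[["snp_id", "a1", "a2"]].rename(columns={"a1": "bim_a1", "a2": "bim_a2"})

    merged = ref.merge(df, on="snp_id", how="inner", suffixes=("", "_sst"))
    merged = merged.merge(bim_min, on="snp_id", how="inner")
    if len(merged) == 0:
        raise DataError(
            "no SNPs shared by summary statistics, LD reference, and target "
            "variant list — check genome build and allele coding"
        )

    signs = np.array(
        [
            _match_alleles(s1, s2, r1, r2)
            for s1, s2, r1, r2 in zip(
                merged["a1"], merged["a2"], merged["ref_a1"], merged["ref_a2"]
            )
        ]
    )
    bim_ok = np.array(
        [
            _match_alleles(b1, b2, r1, r2) != 0
            for b1, b2, r1, r2 in zip(
                merged["bim_a1"], merged["bim_a2"], merged["ref_a1"], merged["ref_a2"]
            )
        ]
    )
    keep = (signs != 0) & bim_ok
    merged = merged.loc[keep]
    if len(merged) == 0:
        raise DataError(
            "allele configurations are irreconcilable for every shared SNP — "
            "likely strand or allele-coding mismatch"
        )

    out = pd.DataFrame(
        {
            "snp_id": merged["snp_id"].to_numpy(),
            "chrom": merged["chrom"].to_numpy(),
            "pos": merged["pos"].to_numpy(dtype=int),
            "a1": merged["ref_a1"].to_numpy(),
            "a2": merged["ref_a2"].to_numpy(),
            "beta_std": merged["beta_std"].to_numpy() * signs[keep],
            "maf": merged["maf"].to_numpy(dtype=float),
        }
    )
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return HarmonizedSumStats(table=out, n=int(n))


QC_RULE_MAF = "maf"
QC_RULE_HWE = "hwe"
QC_RULE_MAF_DIFF = "maf_diff"


def qc_filter(
    variants: pd.DataFrame,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-10,
    maf_diff_max: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant QC: MAF, Hardy–Weinberg, and reference-MAF-difference filters.

    ``variants`` needs columns snp_id and maf; hwe_p and ref_maf are
    optional (their rules are skipped when absent).  Removes variants with
    maf ≤ maf_min, HWE p < hwe_p_min, or |maf − ref_maf| > maf_diff_max.
    Returns (kept variants, exclusion report); the report has one row per
    (variant, violated rule), so per-rule counts sum to the number removed
    whenever the rules fire on disjoint variants.
    """
    if "maf" not in variants.columns or "snp_id" not in variants.columns:
        raise ConfigurationError("qc_filter needs columns snp_id and maf")
    maf = variants["maf"].to_numpy(dtype=float)
    if np.any((maf < 0) | (maf > 0.5)):
        raise DataError("maf outside [0, 0.5]")

    rules: list[tuple[str, np.ndarray]] = [(QC_RULE_MAF, maf <= maf_min)]
    if "hwe_p" in variants.columns:
        hwe = variants["hwe_p"].to_numpy(dtype=float)
        rules.append((QC_RULE_HWE, hwe < hwe_p_min))
    if "ref_maf" in variants.columns:
        ref_maf = variants["ref_maf"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            diff = np.abs(maf - ref_maf)
        rules.append((QC_RULE_MAF_DIFF, diff > maf_diff_max))

    report_rows = []
    removed = np.zeros(len(variants), dtype=bool)
    for rule, mask in rules:
        mask = mask & ~np.isnan(maf)
        removed |= mask
        for sid in variants.loc[mask, "snp_id"]:
            report_rows.append((sid, rule))

    kept = variants.loc[~removed].reset_index(drop=True)
    report = pd.DataFrame(report_rows, columns=["snp_id", "rule"])
    if len(kept) == 0:
        warnings.warn("qc_filter removed every variant", stacklevel=2)
    return kept, report


def write_exclusion_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
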