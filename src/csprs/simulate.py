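"""Synthetic GWAS ecosystem with known ground truth.

Generates everything a polygenic-score run consumes — genotype dosages with
block-structured LD, an additive polygenic phenotype of stated
heritability (quantitative, or binary via the liability-threshold model),
marginal GWAS summary statistics, an LD reference panel, and the target
cohort's files — so the whole pipeline is testable without downloads.

Genotypes: within each LD block a latent Gaussian with AR(1) correlation ρ
is drawn twice per individual (two haplotypes) and thresholded at
Φ⁻¹(maf), so Hardy–Weinberg equilibrium holds by construction and dosages
are 0/1/2.  Between blocks the latent processes are independent, matching
the sampler's block-conditional structure.

Phenotype: a causal subset of round(π·p) SNPs gets effects
β_true ~ N(0, h²/(π·p)) on the standardized-genotype scale;
y = X_std β_true + ε with ε ~ N(0, 1−h²), so Var(Xβ)/Var(y) ≈ h².  Binary
traits threshold the liability at Φ⁻¹(1−K) for prevalence K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .ldref import LDReference, compute_ld_blocks, save_reference

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotype",
    "marginal_gwas",
    "hwe_pvalues",
    "write_fixture_set",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic ecosystem.

    Defaults are the package's standard recovery-study conditions: a GWAS
    cohort of 20,000, 2,000 SNPs in LD blocks of 250 with within-block
    AR(1) correlation 0.5, h² = 0.5 spread over a 5% causal fraction.
    """

    n_gwas: int = 20_000
    n_target: int = 2_000
    n_ref: int = 2_500
    p: int = 2_000
    block_size: int = 250
    rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.5
    causal_frac: float = 0.05
    trait: str = "quantitative"
    prevalence: float = 0.2
    n_chrom: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.rho < 1):
            raise ConfigurationError("rho must lie in [0, 1)")
        if not (0 <= self.h2 <= 1):
            raise ConfigurationError("h2 must lie in [0, 1]")
        if not (0 < self.causal_frac <= 1):
            raise ConfigurationError("causal fraction must lie in (0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.trait not in ("quantitative", "binary"):
            raise ConfigurationError("trait must be 'quantitative' or 'binary'")
        if self.trait == "binary" and not (0 < self.prevalence < 1):
            raise ConfigurationError("prevalence must lie in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth: standardized causal effects and realized quantities."""

    beta_true: np.ndarray
    causal: np.ndarray  # boolean indicator
    realized_h2: float
    maf: np.ndarray = field(repr=False)


def _draw_snp_info(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=config.p)
    a_idx = rng.integers(0, 4, size=config.p)
    shift = rng.integers(1, 4, size=config.p)
    a1 = _BASES[a_idx]
    a2 = _BASES[(a_idx + shift) % 4]

    n_blocks = int(np.ceil(config.p / config.block_size))
    block_of = np.arange(config.p) // config.block_size
    chrom = 1 + (block_of * config.n_chrom) // n_blocks
    # Positions restart per chromosome, spaced 1 kb.
    pos = np.zeros(config.p, dtype=int)
    for c in np.unique(chrom):
        m = chrom == c
        pos[m] = 1 + 1000 * np.arange(m.sum())
    return pd.DataFrame(
        {
            "CHR": chrom.astype(str),
            "SNP": [f"rs{i + 1}" for i in range(config.p)],
            "BP": pos,
            "A1": a1,
            "A2": a2,
            "MAF": maf,
        }
    )


def _ar1_latent(n: int, m: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    if m > 1:
        innov = rng.standard_normal((n, m - 1))
        c = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + c * innov[:, j - 1]
    return z


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator, n: int | None = None,
    snp_info: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Dosage matrix (n × p, int8 in {0,1,2}) plus its SNP info table.

    Pass ``snp_info`` to draw a new cohort at the same variants (same MAFs
    and alleles) — e.g. GWAS, reference, and target cohorts of one study.
    """
    n = n if n is not None else config.n_gwas
    if snp_info is None:
        snp_info = _draw_snp_info(config, rng)
    thresh = stats.norm.ppf(snp_info["MAF"].to_numpy())
    dosage = np.zeros((n, config.p), dtype=np.int8)
    for start in range(0, config.p, config.block_size):
        stop = min(start + config.block_size, config.p)
        m = stop - start
        for _hap in range(2):
            z = _ar1_latent(n, m, config.rho, rng)
            dosage[:, start:stop] += (z < thresh[start:stop]).astype(np.int8)
    return dosage, snp_info


def _standardize_columns(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = dosage.mean(axis=0, dtype=float)
    sd = dosage.std(axis=0, dtype=float)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def simulate_phenotype(
    dosage: np.ndarray, config: SimConfig, rng: np.random.Generator,
    truth: SimTruth | None = None,
) -> tuple[np.ndarray, SimTruth]:
    """Phenotype for a cohort; pass an existing ``truth`` to reuse effects.

    Returns (y, truth).  For binary traits y holds 0/1 case status from
    thresholding the unit-variance liability at Φ⁻¹(1 − prevalence).
    """
    n, p = dosage.shape
    fresh_effects = truth is None
    if fresh_effects:
        m = max(1, round(config.causal_frac * p))
        causal = np.zeros(p, dtype=bool)
        causal[rng.choice(p, size=m, replace=False)] = True
        beta = np.zeros(p)
        beta[causal] = rng.normal(0.0, np.sqrt(config.h2 / (config.causal_frac * p)),
                                  size=m)
        truth = SimTruth(beta_true=beta, causal=causal, realized_h2=np.nan,
                         maf=np.full(p, np.nan))

    mean, sd = _standardize_columns(dosage)
    g = (dosage[:, truth.causal].astype(float) - mean[truth.causal]) / sd[truth.causal]
    genetic = g @ truth.beta_true[truth.causal]
    if fresh_effects and config.h2 > 0 and genetic.std() > 0:
        # Normalize the drawn effects so the genetic variance hits h2 exactly
        # on this cohort; otherwise Var(sum beta^2) ~ h2*sqrt(2/m) would
        # dominate the realized-heritability error at small causal counts.
        scale = np.sqrt(config.h2) / genetic.std()
        truth.beta_true *= scale
        genetic *= scale
    eps = rng.normal(0.0, np.sqrt(max(1.0 - config.h2, 0.0)), size=n)
    liability = genetic + eps
    var_y = liability.var()
    realized_h2 = float(genetic.var() / var_y) if var_y > 0 else 0.0
    maf = np.minimum(dosage.mean(axis=0, dtype=float) / 2.0,
                     1.0 - dosage.mean(axis=0, dtype=float) / 2.0)
    truth = SimTruth(truth.beta_true, truth.causal, realized_h2, maf)

    if config.trait == "binary":
        y = (liability > stats.norm.ppf(1.0 - config.prevalence)).astype(float)
        return y, truth
    return liability, truth


def marginal_gwas(
    dosage: np.ndarray, y: np.ndarray, snp_info: pd.DataFrame,
    trait: str = "quantitative",
) -> pd.DataFrame:
    """Per-SNP single-variant association scan → sumstats frame.

    Quantitative: simple OLS of y on dosage (slope, SE from residual
    variance with n−2 df, two-sided t-test P).  Binary: logistic score
    test at the null (Cochran–Armitage-style trend z), with the one-step
    effect estimate U/V and SE 1/√V.  Columns: SNP A1 A2 BETA SE P.
    """
    X = dosage.astype(float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    xm = X.mean(axis=0)
    sxx = (X * X).sum(axis=0) - n * xm * xm
    sxx = np.where(sxx == 0, np.nan, sxx)
    ym = y.mean()

    if trait == "quantitative":
        sxy = X.T @ y - n * xm * ym
        beta = sxy / sxx
        syy = float(y @ y - n * ym * ym)
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    else:
        u = X.T @ (y - ym)
        v = ym * (1.0 - ym) * sxx
        with np.errstate(divide="ignore", invalid="ignore"):
            z = u / np.sqrt(v)
            beta = u / v
            se = 1.0 / np.sqrt(v)
        pval = 2.0 * stats.norm.sf(np.abs(z))

    pval = np.clip(pval, 1e-323, 1.0)
    return pd.DataFrame(
        {
            "SNP": snp_info["SNP"].to_numpy(),
            "A1": snp_info["A1"].to_numpy(),
            "A2": snp_info["A2"].to_numpy(),
            "BETA": beta,
            "SE": se,
            "P": pval,
        }
    )


def hwe_pvalues(dosage: np.ndarray) -> np.ndarray:
    """Hardy–Weinberg chi-square (1 df) P per SNP from genotype counts."""
    n = dosage.shape[0]
    n2 = (dosage == 2).sum(axis=0).astype(float)
    n1 = (dosage == 1).sum(axis=0).astype(float)
    q = (2 * n2 + n1) / (2 * n)
    exp = np.stack([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    obs = np.stack([n - n1 - n2, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0), axis=0)
    return stats.chi2.sf(chi2, df=1)


def _write_dosage_tsv(path, ids, snp_ids, dosage) -> None:
    df = pd.DataFrame(dosage, columns=snp_ids)
    df.insert(0, "IID", ids)
    df.to_csv(path, sep="\t", index=False)


def _write_bim(path, snp_info: pd.DataFrame) -> None:
    bim = pd.DataFrame(
        {
            0: snp_info["CHR"],
            1: snp_info["SNP"],
            2: 0,
            3: snp_info["BP"],
            4: snp_info["A1"],
            5: snp_info["A2"],
        }
    )
    bim.to_csv(path, sep="\t", header=False, index=False)


def write_fixture_set(directory, config: SimConfig) -> dict:
    """Materialize a full synthetic study on disk; returns paths + truth.

    Writes sumstats.tsv (GWAS scan), an LD reference directory (built from
    an independent reference cohort), target.bim + target_dosage.tsv +
    target_pheno.tsv (held-out cohort with phenotype and two null
    covariates), and truth arrays for validation.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    gwas_dos, snp_info = simulate_genotypes(config, rng, n=config.n_gwas)
    y_gwas, truth = simulate_phenotype(gwas_dos, config, rng)
    sst = marginal_gwas(gwas_dos, y_gwas, snp_info, trait=config.trait)
    sst.to_csv(d / "sumstats.tsv", sep="\t", index=False)
    del gwas_dos

    ref_dos, _ = simulate_genotypes(config, rng, n=config.n_ref, snp_info=snp_info)
    info = snp_info.copy()
    info["MAF"] = np.minimum(ref_dos.mean(axis=0) / 2.0, 1 - ref_dos.mean(axis=0) / 2.0)
    ref = compute_ld_blocks(ref_dos, info, block_size=config.block_size)
    ref_dir = d / "ldref"
    save_reference(ref, ref_dir)
    del ref_dos

    tgt_dos, _ = simulate_genotypes(config, rng, n=config.n_target, snp_info=snp_info)
    y_tgt, truth = simulate_phenotype(tgt_dos, config, rng, truth=truth)
    ids = [f"ind{i + 1}" for i in range(config.n_target)]
    _write_bim(d / "target.bim", snp_info)
    _write_dosage_tsv(d / "target_dosage.tsv", ids, list(snp_info["SNP"]), tgt_dos)
    pheno = pd.DataFrame(
        {
            "id": ids,
            "phenotype": y_tgt,
            "sex": rng.integers(0, 2, size=config.n_target),
            "age": rng.normal(50, 10, size=config.n_target).round(1),
        }
    )
    pheno.to_csv(d / "target_pheno.tsv", sep="\t", index=False)

    np.savetxt(d / "beta_true.tsv", truth.beta_true)
    return {
        "sumstats": d / "sumstats.tsv",
        "ref_dir": ref_dir,
        "bim": d / "target.bim",
        "dosage": d / "target_dosage.tsv",
        "pheno": d / "target_pheno.tsv",
        "truth": truth,
        "snp_info": snp_info,
    }


def simulate_reference(config: SimConfig, rng: np.random.Generator,
                       snp_info: pd.DataFrame | None = None) -> LDReference:
    """In-memory LD reference from a fresh reference cohort."""
    dos, info = simulate_genotypes(config, rng, n=config.n_ref, snp_info=snp_info)
    info = info.copy()
    info["MAF"] = np.minimum(dos.mean(axis=0) / 2.0, 1 - dos.mean(axis=0) / 2.0)
    return compute_ld_blocks(dos, info, block_size=config.block_size)
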