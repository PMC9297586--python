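"""Block-wise Gibbs sampler under the global-local continuous-shrinkage prior.

Model, on the standardized scale: marginal GWAS effects β̂ relate to true
effects β through the LD matrix, β̂ | β ~ N(Dβ, (σ²/n)·D-ish); the prior on
each SNP effect is the scale mixture

    β_j | ψ_j, σ², φ  ~  N(0, (σ²/n) φ ψ_j),
    ψ_j ~ Gamma(a, δ_j),   δ_j ~ Gamma(b, φ),

a global-local prior (shapes a, b; default a=1, b=1/2 gives the
horseshoe-like Strawderman–Berger behavior) that shrinks null effects hard
while leaving large effects nearly unbiased.  The global scale φ is fixed
or learned from the data ("auto").

Full conditionals, swept block by block in genomic order:

    β_blk  ~ N(A⁻¹ β̂_blk, (σ²/n) A⁻¹),          A = D_blk + diag(1/ψ_blk)
    ψ_j    ~ GIG(a − ½, 2δ_j, n β_j²/σ²), capped at 1
    δ_j    ~ Gamma(a + b, rate ψ_j + φ)
    φ      ~ Gamma(p·b + ½, rate Σδ + w), w ~ Gamma(1, rate φ_old + 1)   [auto]
    1/σ²   ~ Gamma((n + p)/2, rate e),
             e = max( (n/2)(1 − 2βᵀβ̂ + Σ_blk βᵀ(D + diag(1/ψ))β),
                      (n/2) Σ_j β_j²/ψ_j )

The posterior mean of β over retained draws is the SNP weight vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ConfigurationError, NumericalError
from .gig import sample_gig
from .ldref import LDBlock, LDReference
from .sumstats import HarmonizedSumStats

__all__ = [
    "PriorConfig",
    "MCMCConfig",
    "GibbsState",
    "PosteriorWeights",
    "update_beta",
    "update_psi_delta",
    "update_phi_auto",
    "update_sigma2",
    "run_mcmc",
]

AUTO = "auto"

# The paper-scale preset: 10,000 iterations with proportional burn-in/thinning.
PRESET_FULL = dict(n_iter=10_000, n_burnin=5_000, thin=5)


@dataclass
class PriorConfig:
    """Continuous-shrinkage prior hyperparameters.

    a: local-scale shape (>0).  b: coupler shape (>0).  phi: global
    shrinkage — a positive float, or "auto" to sample it.
    """

    a: float = 1.0
    b: float = 0.5
    phi: Union[float, str] = AUTO

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ConfigurationError("prior shapes a and b must be positive")
        if not self.auto_phi and float(self.phi) <= 0:
            raise ConfigurationError("fixed phi must be positive")

    @property
    def auto_phi(self) -> bool:
        return isinstance(self.phi, str) and self.phi.lower() == AUTO


@dataclass
class MCMCConfig:
    n_iter: int = 1000
    n_burnin: int = 500
    thin: int = 5
    seed: int = 0
    chains: int = 1

    def __post_init__(self):
        if self.n_burnin >= self.n_iter:
            raise ConfigurationError("n_burnin must be smaller than n_iter")
        if self.thin < 1 or (self.n_iter - self.n_burnin) // self.thin < 1:
            raise ConfigurationError("need at least one retained draw")
        if self.chains < 1:
            raise ConfigurationError("chains must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


@dataclass
class GibbsState:
    """Current sampler state (β, ψ, δ, σ², φ) for one chromosome chain."""

    beta: np.ndarray
    psi: np.ndarray
    delta: np.ndarray
    sigma2: float
    phi: float

    @classmethod
    def initial(cls, p: int, phi: float = 1.0) -> "GibbsState":
        return cls(
            beta=np.zeros(p),
            psi=np.ones(p),
            delta=np.ones(p),
            sigma2=1.0,
            phi=float(phi),
        )


@dataclass
class PosteriorWeights:
    """Posterior-mean SNP weights plus chain diagnostics.

    ``table`` columns: CHR, SNP, BP, A1, A2, BETA (posterior mean on the
    requested scale).  ``beta_var`` is the per-SNP sample variance of the
    retained standardized draws; ``n_retained`` the retained draw count —
    together they give a Monte-Carlo error scale for each weight.
    """

    table: pd.DataFrame
    beta_var: np.ndarray = field(repr=False)
    n_retained: int = 0
    phi_mean: float = float("nan")
    sigma2_mean: float = float("nan")

    @property
    def beta(self) -> np.ndarray:
        return self.table["BETA"].to_numpy()

    def write(self, path) -> None:
        """Header-less 6-column TSV (CHR SNP BP A1 A2 BETA)."""
        self.table.to_csv(path, sep="\t", header=False, index=False,
                          float_format="%.10e")


def _chol_with_jitter(A: np.ndarray, label: str):
    """Lower Cholesky factor of A, adding doubling diagonal jitter on failure."""
    eps = 1e-6 * np.trace(A) / A.shape[0]
    for attempt in range(7):
        try:
            return linalg.cholesky(A, lower=True)
        except linalg.LinAlgError:
            A = A + np.eye(A.shape[0]) * eps
            eps *= 2.0
    raise NumericalError(f"Cholesky factorization failed for {label} after max jitter")


def update_beta(
    state: GibbsState,
    block: LDBlock | np.ndarray,
    beta_hat_blk: np.ndarray,
    idx: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the block's β from N(A⁻¹β̂, (σ²/n)A⁻¹), A = D + diag(1/ψ).

    Uses the lower-triangular factorization A = LLᵀ: mean solves A m = β̂,
    and L⁻ᵀ z has covariance A⁻¹ for z ~ N(0, I).  Writes the draw into
    ``state.beta[idx]`` and returns it.
    """
    D = block.D if isinstance(block, LDBlock) else np.asarray(block)
    psi_blk = state.psi[idx]
    if np.any(psi_blk <= 0):
        raise NumericalError("psi must be strictly positive in update_beta")
    A = D + np.diag(1.0 / psi_blk)
    label = f"block at SNPs {idx[0]}..{idx[-1]}"
    L = _chol_with_jitter(A, label)
    mean = linalg.cho_solve((L, True), beta_hat_blk)
    z = rng.standard_normal(len(beta_hat_blk))
    draw = mean + np.sqrt(state.sigma2 / n) * linalg.solve_triangular(L.T, z, lower=False)
    state.beta[idx] = draw
    return draw


def update_psi_delta(
    state: GibbsState, n: int, prior: PriorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Local scales: ψ_j ~ GIG(a−½, 2δ_j, nβ_j²/σ²) capped at 1, then
    δ_j ~ Gamma(a+b, rate ψ_j + φ)."""
    chi = n * state.beta**2 / state.sigma2
    psi = sample_gig(prior.a - 0.5, 2.0 * state.delta, chi, rng)
    psi = np.minimum(np.asarray(psi, dtype=float), 1.0)
    delta = rng.gamma(prior.a + prior.b, 1.0 / (psi + state.phi))
    state.psi = psi
    state.delta = delta
    return psi, delta


def update_phi_auto(state: GibbsState, prior: PriorConfig, rng: np.random.Generator) -> float:
    """Global scale via its auxiliary-variable conjugate update."""
    w = rng.gamma(1.0, 1.0 / (state.phi + 1.0))
    p = len(state.delta)
    phi = rng.gamma(p * prior.b + 0.5, 1.0 / (np.sum(state.delta) + w))
    state.phi = float(phi)
    return state.phi


def update_sigma2(
    state: GibbsState,
    beta_hat: np.ndarray,
    blocks: list[tuple[np.ndarray, np.ndarray]],
    n: int,
    rng: np.random.Generator,
) -> float:
    """Residual variance: 1/σ² ~ Gamma((n+p)/2, rate e).

    ``blocks`` is a list of (index array, D matrix) pairs.  The rate uses
    the guard e = max(quadratic-form expression, (n/2)Σβ²/ψ) so it stays
    positive whenever β ≠ 0.
    """
    beta = state.beta
    p = len(beta)
    quad = 0.0
    for idx, D in blocks:
        b = beta[idx]
        quad += float(b @ D @ b)
    ridge = float(np.sum(beta**2 / state.psi))
    e = max(
        (n / 2.0) * (1.0 - 2.0 * float(beta @ beta_hat) + quad + ridge),
        (n / 2.0) * ridge,
    )
    if not np.isfinite(e):
        raise NumericalError("non-finite rate in sigma2 update")
    inv = rng.gamma((n + p) / 2.0, 1.0 / e)
    state.sigma2 = float(1.0 / inv)
    return state.sigma2


def _chrom_seed_key(chrom: str) -> int:
    """Stable small integer derived from a chromosome label."""
    try:
        return int(chrom)
    except ValueError:
        return sum((i + 1) * ord(c) for i, c in enumerate(str(chrom))) % 100_000


def run_chromosome(
    chrom: str,
    beta_hat: np.ndarray,
    blocks: list[tuple[np.ndarray, np.ndarray]],
    n: int,
    prior: PriorConfig,
    mcmc: MCMCConfig,
) -> dict:
    """Run the Gibbs chain for one chromosome; deterministic given the seed.

    RNG stream is derived from (seed, chromosome), so per-chromosome runs
    are reproducible independently and parallel execution cannot change
    results.  Returns running posterior means of β (and φ, σ²) plus the
    per-SNP Welford variance of retained draws.
    """
    p = len(beta_hat)
    rng = np.random.default_rng([int(mcmc.seed), _chrom_seed_key(chrom)])
    state = GibbsState.initial(p, phi=1.0 if prior.auto_phi else float(prior.phi))

    beta_mean = np.zeros(p)
    beta_m2 = np.zeros(p)
    phi_sum = 0.0
    sig_sum = 0.0
    kept = 0

    for it in range(1, mcmc.n_iter + 1):
        for idx, D in blocks:
            update_beta(state, D, beta_hat[idx], idx, n, rng)
        update_psi_delta(state, n, prior, rng)
        if prior.auto_phi:
            update_phi_auto(state, prior, rng)
        update_sigma2(state, beta_hat, blocks, n, rng)

        if not np.all(np.isfinite(state.beta)):
            raise NumericalError(f"NaN/Inf in chain for chr{chrom} at iteration {it}")

        if it > mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
            kept += 1
            d = state.beta - beta_mean
            beta_mean += d / kept
            beta_m2 += d * (state.beta - beta_mean)
            phi_sum += state.phi
            sig_sum += state.sigma2

    beta_var = beta_m2 / (kept - 1) if kept > 1 else np.full(p, np.nan)
    return {
        "chrom": chrom,
        "beta_mean": beta_mean,
        "beta_var": beta_var,
        "n_retained": kept,
        "phi_mean": phi_sum / kept,
        "sigma2_mean": sig_sum / kept,
    }


def run_mcmc(
    sumstats: HarmonizedSumStats,
    ref: LDReference,
    prior: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
    beta_scale: str = "standardized",
    n_jobs: int = 1,
) -> PosteriorWeights:
    """Posterior SNP weights for the harmonized analysis set.

    Chromosomes are independent chains (independent seeded RNG streams);
    ``n_jobs`` > 1 runs them in parallel processes with identical results.
    ``beta_scale`` is "standardized" or "per-allele" (standardized weight
    divided by √(2·maf·(1−maf))).
    """
    prior = prior or PriorConfig()
    mcmc = mcmc or MCMCConfig()
    if beta_scale not in ("standardized", "per-allele"):
        raise ConfigurationError("beta_scale must be 'standardized' or 'per-allele'")

    tab = sumstats.table
    ref = ref.subset_to(list(tab["snp_id"]))
    order = [s for b in ref.blocks for s in b.snp_ids]
    tab = tab.set_index("snp_id").loc[order].reset_index()
    beta_hat_all = tab["beta_std"].to_numpy()

    jobs = []
    offset = 0
    for chrom in ref.chromosomes():
        blocks = []
        start = offset
        for b in ref.blocks_for(chrom):
            idx = np.arange(offset - start, offset - start + b.size)
            blocks.append((idx, b.D))
            offset += b.size
        jobs.append((chrom, beta_hat_all[start:offset], blocks))

    if n_jobs > 1 and len(jobs) > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(run_chromosome)(c, bh, blks, sumstats.n, prior, mcmc)
            for c, bh, blks in jobs
        )
    else:
        results = [
            run_chromosome(c, bh, blks, sumstats.n, prior, mcmc) for c, bh, blks in jobs
        ]

    beta_post = np.concatenate([r["beta_mean"] for r in results])
    beta_var = np.concatenate([r["beta_var"] for r in results])
    maf = tab["maf"].to_numpy(dtype=float)
    if beta_scale == "per-allele":
        denom = np.sqrt(2.0 * maf * (1.0 - maf))
        if np.any(denom == 0):
            warnings.warn("monomorphic MAF in per-allele rescaling", stacklevel=2)
        beta_out = beta_post / denom
    else:
        beta_out = beta_post

    table = pd.DataFrame(
        {
            "CHR": tab["chrom"].to_numpy(),
            "SNP": tab["snp_id"].to_numpy(),
            "BP": tab["pos"].to_numpy(),
            "A1": tab["a1"].to_numpy(),
            "A2": tab["a2"].to_numpy(),
            "BETA": beta_out,
        }
    )
    n_ret = results[0]["n_retained"]
    return PosteriorWeights(
        table=table,
        beta_var=beta_var,
        n_retained=n_ret,
        phi_mean=float(np.mean([r["phi_mean"] for r in results])),
        sigma2_mean=float(np.mean([r["sigma2_mean"] for r in results])),
    )
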