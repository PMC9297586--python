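"""PRS accuracy metrics and the cross-run concordance protocol.

Quantitative traits: ordinary least squares R² of the phenotype on the
scaled score plus covariates (full-model R², with incremental R² over the
covariates-only model reported alongside).  Binary traits: AUC of the
score, Nagelkerke pseudo-R² from nested logistic fits, and the odds ratio
of the top 10% of scores versus the bottom 90%.  Replicate runs are
summarized as mean (SD).  Concordance between two weight vectors (e.g. two
chains, or two implementations) is the per-SNP squared error plus a paired
t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import DataError, NumericalError

__all__ = [
    "EvalResult",
    "ConcordanceResult",
    "r2_quantitative",
    "auc",
    "nagelkerke_r2",
    "top_decile_or",
    "concordance",
    "replicate_summary",
]


@dataclass
class EvalResult:
    metric: str
    value: float
    sd: float | None = None
    n: int = 0
    cases: int | None = None
    controls: int | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class ConcordanceResult:
    squared_errors: np.ndarray = field(repr=False)
    median_sq_error: float = float("nan")
    t_stat: float = float("nan")
    p_value: float = float("nan")
    n_snps: int = 0


def _design(z: np.ndarray, covariates: pd.DataFrame | np.ndarray | None,
            include_score: bool) -> np.ndarray:
    cols = [np.ones(len(z))]
    names = ["const"]
    if covariates is not None:
        C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) \
            else np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        for k in range(C.shape[1]):
            cols.append(C[:, k])
            names.append(
                covariates.columns[k] if isinstance(covariates, pd.DataFrame) else f"cov{k}"
            )
    if include_score:
        cols.append(np.asarray(z, dtype=float))
        names.append("score")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # Identify offending columns by incremental rank growth.
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise DataError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X


def r2_quantitative(z_scores, phenotype, covariates=None) -> EvalResult:
    """OLS R² of phenotype ~ score + covariates.

    ``value`` is the full-model R²; ``extras['incremental_r2']`` is the gain
    over the covariates-only model.
    """
    z = np.asarray(z_scores, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = np.isfinite(z) & np.isfinite(y)
    if covariates is not None:
        C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) \
            else np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        ok &= np.all(np.isfinite(C), axis=1)
        covariates = pd.DataFrame(C[ok], columns=getattr(covariates, "columns",
                                  [f"cov{k}" for k in range(C.shape[1])]))
    z, y = z[ok], y[ok]
    if len(y) < 3:
        raise DataError("need at least 3 complete cases")

    full = sm.OLS(y, _design(z, covariates, include_score=True)).fit()
    if covariates is not None:
        null = sm.OLS(y, _design(z, covariates, include_score=False)).fit()
        inc = full.rsquared - null.rsquared
    else:
        inc = full.rsquared
    return EvalResult("r2", float(full.rsquared), n=len(y),
                      extras={"incremental_r2": float(inc)})


def auc(z_scores, labels) -> EvalResult:
    """AUC via the rank (Mann–Whitney) formulation; ties count 1/2."""
    z = np.asarray(z_scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise DataError("AUC needs exactly two classes in the labels")
    y01 = (y == classes.max()).astype(int)
    val = float(roc_auc_score(y01, z))
    return EvalResult("auc", val, n=len(y), cases=int(y01.sum()),
                      controls=int(len(y) - y01.sum()))


def nagelkerke_r2(z_scores, labels, covariates=None) -> EvalResult:
    """Nagelkerke pseudo-R²: (1 − (L0/L1)^{2/n}) / (1 − L0^{2/n}).

    L1 is the maximized likelihood of the covariates+score logistic model,
    L0 of the covariates-only (or intercept-only) model.
    """
    z = np.asarray(z_scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) != 2:
        raise DataError("Nagelkerke R² needs a binary outcome")
    y = (y == y.max()).astype(float)
    n = len(y)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(y, _design(z, covariates, True)).fit(disp=0, maxiter=200)
            null = sm.Logit(y, _design(z, covariates, False)).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises several convergence types
        raise NumericalError(f"logistic fit failed (separation?): {exc}") from exc
    if not (np.isfinite(full.llf) and np.isfinite(null.llf)):
        raise NumericalError("logistic likelihood non-finite; check for separation")
    cox_snell = 1.0 - np.exp(2.0 / n * (null.llf - full.llf))
    max_cs = 1.0 - np.exp(2.0 / n * null.llf)
    val = float(cox_snell / max_cs)
    val = min(max(val, 0.0), 1.0)
    return EvalResult("nagelkerke_r2", val, n=n, cases=int(y.sum()),
                      controls=int(n - y.sum()))


def top_decile_or(z_scores, labels) -> EvalResult:
    """Odds ratio of case status, top 10% of scores vs bottom 90%.

    The stratum boundary is the 90th percentile of scores; subjects tied at
    the boundary value go to the top stratum.  Zero cells get the
    Haldane–Anscombe 0.5 correction (with a warning).
    """
    z = np.asarray(z_scores, dtype=float)
    y = np.asarray(labels)
    if len(z) < 10:
        raise DataError("top-decile OR needs at least 10 subjects")
    classes = np.unique(y)
    if len(classes) != 2:
        raise DataError("top-decile OR needs both classes present")
    y01 = (y == classes.max()).astype(int)
    cut = np.quantile(z, 0.9)
    top = z >= cut
    if top.all() or not top.any():
        raise DataError("decile split put all subjects in one stratum")
    a = float(np.sum(top & (y01 == 1)))      # cases, top
    b = float(np.sum(top & (y01 == 0)))      # controls, top
    c = float(np.sum(~top & (y01 == 1)))     # cases, bottom
    d = float(np.sum(~top & (y01 == 0)))     # controls, bottom
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
        warnings.warn("zero cell in top-decile 2x2 table; Haldane–Anscombe "
                      "0.5 correction applied", stacklevel=2)
    val = (a * d) / (b * c)
    return EvalResult("top_decile_or", float(val), n=len(z),
                      cases=int(y01.sum()), controls=int(len(z) - y01.sum()),
                      extras={"zero_cell_corrected": corrected})


def concordance(weights_a: pd.DataFrame, weights_b: pd.DataFrame) -> ConcordanceResult:
    """Per-SNP squared error and paired t-test between two weight tables.

    Inputs are weight frames with columns SNP and BETA (id-joined); the SNP
    sets must be identical.
    """
    a = weights_a.set_index("SNP")["BETA"]
    b = weights_b.set_index("SNP")["BETA"]
    sym_diff = set(a.index) ^ set(b.index)
    if sym_diff:
        raise DataError(f"weight SNP sets differ; symmetric difference e.g. "
                        f"{sorted(sym_diff)[:5]} ({len(sym_diff)} total)")
    if len(a) < 2:
        raise DataError("concordance needs at least 2 SNPs")
    b = b.loc[a.index]
    wa, wb = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    sq = (wa - wb) ** 2
    diffs = wa - wb
    if np.allclose(diffs, diffs[0]):
        # Constant difference (incl. identical inputs): t-test variance is 0.
        t, p = (0.0, 1.0) if diffs[0] == 0 else (np.inf, 0.0)
    else:
        t, p = stats.ttest_rel(wa, wb)
    return ConcordanceResult(squared_errors=sq, median_sq_error=float(np.median(sq)),
                             t_stat=float(t), p_value=float(p), n_snps=len(sq))


def replicate_summary(values) -> tuple[float, float]:
    """Mean and sample SD (denominator k−1) across k replicate metric values."""
    v = np.asarray(list(values), dtype=float)
    if len(v) == 0:
        raise DataError("replicate_summary needs at least one value")
    if len(v) == 1:
        warnings.warn("single replicate; SD reported as NaN", stacklevel=2)
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1))
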