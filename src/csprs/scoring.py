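"""Individual-level polygenic scores from posterior SNP weights.

A score is the weighted allele sum raw_i = Σ_j w_j · d_ij, where d_ij
counts copies of the weight's effect allele (A1) in individual i.  Allele
alignment between the weight file and the genotype coding reuses the same
four-configuration logic as sumstats harmonization; a swapped coding counts
2 − d toward the weight's A1, so raw scores are identical to direct coding.
Scores are then z-scaled (sample SD, matching R's scale()).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .gibbs import PosteriorWeights
from .sumstats import _match_alleles, read_bim

__all__ = ["GenotypeData", "ScoreTable", "score", "align_weight_alleles",
           "load_genotypes", "read_weights"]


@dataclass
class GenotypeData:
    """Dosage matrix (individuals × SNPs) with per-variant allele coding.

    ``dosages`` counts copies of ``a1``; values in [0, 2], NaN = missing.
    """

    ids: list[str]
    snp_ids: list[str]
    a1: list[str]
    a2: list[str]
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self):
        n, p = self.dosages.shape
        if n != len(self.ids) or p != len(self.snp_ids):
            raise DataError("dosage matrix shape does not match ids/snp_ids")


@dataclass
class ScoreTable:
    """Per-individual raw and z-scaled scores."""

    table: pd.DataFrame  # columns: id, raw_score, z_score

    @property
    def z(self) -> np.ndarray:
        return self.table["z_score"].to_numpy()

    @property
    def raw(self) -> np.ndarray:
        return self.table["raw_score"].to_numpy()

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_genotypes(dosage_tsv, bim_path) -> GenotypeData:
    """Load a dosage TSV (first column IID, one column per SNP) plus its .bim.

    The .bim supplies each SNP's counted allele (A1) and other allele.
    """
    df = pd.read_csv(dosage_tsv, sep="\t")
    if df.shape[1] < 2:
        raise DataError(f"{dosage_tsv}: expected an IID column plus SNP columns")
    ids = df.iloc[:, 0].astype(str).tolist()
    snp_ids = list(df.columns[1:])
    dos = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.nanmin(dos) < 0 or np.nanmax(dos) > 2:
        raise DataError(f"{dosage_tsv}: dosages must lie in [0, 2]")
    bim = read_bim(bim_path).set_index("snp_id")
    missing = [s for s in snp_ids if s not in bim.index]
    if missing:
        raise DataError(f"SNPs absent from {bim_path}: {missing[:5]}")
    a1 = [bim.loc[s, "a1"] for s in snp_ids]
    a2 = [bim.loc[s, "a2"] for s in snp_ids]
    return GenotypeData(ids, snp_ids, a1, a2, dos)


def read_weights(path) -> pd.DataFrame:
    """Read one or more 6-column header-less weight files (CHR SNP BP A1 A2 BETA)."""
    paths = [path] if isinstance(path, (str, Path)) else list(path)
    frames = [
        pd.read_csv(p, sep="\t", header=None,
                    names=["CHR", "SNP", "BP", "A1", "A2", "BETA"],
                    dtype={"CHR": str, "SNP": str, "A1": str, "A2": str})
        for p in paths
    ]
    return pd.concat(frames, ignore_index=True)


def align_weight_alleles(
    weights: pd.DataFrame, genotypes: GenotypeData
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Match weight SNPs to genotype columns and resolve allele coding.

    Returns (weight values, genotype column indices, flip mask, n_excluded):
    flipped SNPs count 2 − d toward the weight's A1.  SNPs with
    irreconcilable alleles are excluded with a warning.
    """
    col_of = {s: j for j, s in enumerate(genotypes.snp_ids)}
    w_vals, cols, flips = [], [], []
    excluded = 0
    for _, row in weights.iterrows():
        j = col_of.get(row["SNP"])
        if j is None:
            continue
        sign = _match_alleles(
            str(row["A1"]).upper(), str(row["A2"]).upper(),
            genotypes.a1[j].upper(), genotypes.a2[j].upper(),
        )
        if sign == 0:
            excluded += 1
            continue
        w_vals.append(float(row["BETA"]))
        cols.append(j)
        flips.append(sign < 0)
    if not cols:
        raise DataError("no weight SNPs overlap the genotype data after allele matching")
    if excluded:
        warnings.warn(f"{excluded} weight SNPs excluded: irreconcilable alleles",
                      stacklevel=2)
    return (np.array(w_vals), np.array(cols, dtype=int),
            np.array(flips, dtype=bool), excluded)


def score(
    weights: PosteriorWeights | pd.DataFrame,
    genotypes: GenotypeData,
    missing: str = "impute",
) -> ScoreTable:
    """Weighted allele sums, z-scaled to mean 0 and unit (sample) SD.

    Missing dosages are imputed with the cohort mean of the counted allele
    dosage for that SNP (``missing="impute"``), or the SNP is dropped for
    the affected individuals' sum (``missing="drop"``, i.e. treated as 0
    after centering is not applied — the weight simply does not contribute).
    """
    wtab = weights.table if isinstance(weights, PosteriorWeights) else weights
    w, cols, flips, _ = align_weight_alleles(wtab, genotypes)

    d = genotypes.dosages[:, cols].astype(float)
    d[:, flips] = 2.0 - d[:, flips]
    nan = np.isnan(d)
    if nan.any():
        if missing == "impute":
            col_mean = np.nanmean(d, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            d = np.where(nan, col_mean[None, :], d)
        elif missing == "drop":
            d = np.where(nan, 0.0, d)
        else:
            raise DataError(f"unknown missing-dosage policy '{missing}'")

    raw = d @ w
    if len(np.unique(raw)) >= 2:
        z = (raw - raw.mean()) / raw.std(ddof=1)
    else:
        warnings.warn("all raw scores identical; z-scores set to 0", stacklevel=2)
        z = np.zeros_like(raw)
    return ScoreTable(pd.DataFrame({"id": genotypes.ids, "raw_score": raw, "z_score": z}))
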