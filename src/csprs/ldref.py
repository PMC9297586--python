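"""Blocked LD reference: construction, subsetting, and on-disk container.

The sampler conditions on one correlation matrix D per LD block.  Blocks
partition the reference SNP set; between-block correlation is treated as
zero, which is what makes the block-wise Gibbs update exact under the
model.  On disk a reference is a directory holding ``snpinfo.tsv`` plus one
HDF5 file per block (datasets ``D`` and ``snp_ids``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "LDBlock",
    "LDReference",
    "compute_ld_blocks",
    "load_reference",
    "save_reference",
]

SNPINFO_COLUMNS = ["CHR", "SNP", "BP", "A1", "A2", "MAF"]


@dataclass
class LDBlock:
    """One LD block: ordered SNP ids and their correlation matrix."""

    snp_ids: list[str]
    D: np.ndarray
    chrom: str = "1"

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise DataError(
                f"block on chr{self.chrom}: D is {self.D.shape} for "
                f"{len(self.snp_ids)} SNPs"
            )

    @property
    def size(self) -> int:
        return len(self.snp_ids)

    def validate(self, eig_tol: float = 1e-8) -> None:
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise DataError(f"block on chr{self.chrom}: D is not symmetric")
        if not np.all(np.diag(self.D) == 1.0):
            raise DataError(f"block on chr{self.chrom}: diag(D) != 1")
        if self.size and np.linalg.eigvalsh(self.D).min() < -eig_tol:
            raise DataError(f"block on chr{self.chrom}: D is not PSD within tolerance")


@dataclass
class LDReference:
    """Ordered LD blocks plus the SNP info table (CHR SNP BP A1 A2 MAF)."""

    blocks: list[LDBlock]
    snp_info: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        block_snps = [s for b in self.blocks for s in b.snp_ids]
        if len(block_snps) != len(set(block_snps)):
            raise DataError("a SNP appears in more than one LD block")
        info_snps = list(self.snp_info["SNP"])
        if set(block_snps) != set(info_snps):
            raise DataError("LD blocks do not partition the snpinfo SNP set")

    @property
    def n_snps(self) -> int:
        return len(self.snp_info)

    @property
    def snp_ids(self) -> list[str]:
        return [s for b in self.blocks for s in b.snp_ids]

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for b in self.blocks:
            if b.chrom not in seen:
                seen.append(b.chrom)
        return seen

    def blocks_for(self, chrom: str) -> list[LDBlock]:
        return [b for b in self.blocks if b.chrom == str(chrom)]

    def subset_to(self, snp_ids) -> "LDReference":
        """Restrict to the given SNP set; block structure and order preserved.

        Rows/columns of each D are subset in place; blocks left empty are
        dropped.  Every requested SNP must exist in the reference.
        """
        want = set(snp_ids)
        have = set(self.snp_info["SNP"])
        missing = want - have
        if missing:
            raise DataError(
                f"{len(missing)} SNPs not in the LD reference, e.g. "
                f"{sorted(missing)[:5]}"
            )
        new_blocks = []
        for b in self.blocks:
            idx = [i for i, s in enumerate(b.snp_ids) if s in want]
            if not idx:
                continue
            sub = b.D[np.ix_(idx, idx)]
            new_blocks.append(LDBlock([b.snp_ids[i] for i in idx], sub, b.chrom))
        info = self.snp_info[self.snp_info["SNP"].isin(want)].reset_index(drop=True)
        return LDReference(new_blocks, info)


def compute_ld_blocks(
    dosages: np.ndarray,
    snp_info: pd.DataFrame,
    boundaries: pd.DataFrame | None = None,
    block_size: int = 1000,
) -> LDReference:
    """Pearson-correlation LD blocks from a dosage matrix (individuals × SNPs).

    ``snp_info`` (CHR SNP BP A1 A2 MAF) must be column-ordered by position
    within chromosome.  Blocks come from ``boundaries`` (columns chr, start,
    end; 1-based inclusive positions) when given, else from fixed windows of
    ``block_size`` SNPs per chromosome.
    """
    X = np.asarray(dosages, dtype=float)
    if X.shape[1] != len(snp_info):
        raise DataError("dosage columns do not match snp_info rows")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = snp_info["SNP"].iloc[int(np.flatnonzero(sd == 0)[0])]
        raise DataError(f"constant dosage column for SNP {bad}; cannot correlate")

    chroms = snp_info["CHR"].astype(str).to_numpy()
    pos = snp_info["BP"].to_numpy(dtype=int)

    blocks: list[LDBlock] = []
    assigned = np.zeros(len(snp_info), dtype=bool)
    for chrom in pd.unique(chroms):
        on_chr = np.flatnonzero(chroms == chrom)
        if boundaries is not None:
            bnd = boundaries[boundaries["chr"].astype(str) == chrom]
            spans = [
                np.flatnonzero((chroms == chrom) & (pos >= s) & (pos <= e))
                for s, e in zip(bnd["start"], bnd["end"])
            ]
        else:
            spans = [on_chr[i : i + block_size] for i in range(0, len(on_chr), block_size)]
        for idx in spans:
            if len(idx) == 0:
                continue
            D = np.corrcoef(X[:, idx], rowvar=False)
            D = np.atleast_2d(D)
            np.fill_diagonal(D, 1.0)
            D = (D + D.T) / 2.0
            blocks.append(LDBlock(list(snp_info["SNP"].iloc[idx]), D, str(chrom)))
            assigned[idx] = True
    if not np.all(assigned):
        bad = snp_info["SNP"].iloc[int(np.flatnonzero(~assigned)[0])]
        raise DataError(f"block boundaries do not cover SNP {bad}")
    return LDReference(blocks, snp_info.reset_index(drop=True))


_BLOCK_RE = re.compile(r"ldblk_(\d+)_chr(.+)\.h5$")


def save_reference(ref: LDReference, directory) -> None:
    """Write ``snpinfo.tsv`` plus one ``ldblk_<idx>_chr<c>.h5`` per block."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ref.snp_info.to_csv(d / "snpinfo.tsv", sep="\t", index=False)
    for i, b in enumerate(ref.blocks):
        with h5py.File(d / f"ldblk_{i:05d}_chr{b.chrom}.h5", "w") as f:
            f.create_dataset("D", data=b.D, dtype="f8")
            f.create_dataset(
                "snp_ids", data=np.array(b.snp_ids, dtype=h5py.string_dtype())
            )


def load_reference(directory) -> LDReference:
    """Load a reference directory written by :func:`save_reference`."""
    d = Path(directory)
    info_path = d / "snpinfo.tsv"
    if not info_path.exists():
        raise DataError(f"{d} has no snpinfo.tsv — not an LD reference directory")
    snp_info = pd.read_csv(info_path, sep="\t", dtype={"SNP": str, "CHR": str})
    files = sorted(d.glob("ldblk_*_chr*.h5"))
    if not files:
        raise DataError(f"{d} holds no LD block files")
    blocks = []
    for path in files:
        m = _BLOCK_RE.search(path.name)
        if not m:
            raise DataError(f"unrecognized LD block file name: {path.name}")
        try:
            with h5py.File(path, "r") as f:
                D = f["D"][()]
                snp_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["snp_ids"][()]]
        except (OSError, KeyError) as exc:
            raise DataError(f"malformed LD block file {path.name}: {exc}") from exc
        blk = LDBlock(snp_ids, D, m.group(2))
        blk.validate()
        blocks.append(blk)
    return LDReference(blocks, snp_info)
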