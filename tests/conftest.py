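import numpy as np
import pandas as pd
import pytest

from csprs.simulate import (
    SimConfig,
    marginal_gwas,
    simulate_genotypes,
    simulate_phenotype,
    simulate_reference,
)
from csprs.sumstats import harmonize


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Scaled-down study for fast unit tests."""
    return SimConfig(
        n_gwas=4000, n_target=600, n_ref=1500, p=240, block_size=60,
        rho=0.5, h2=0.5, causal_frac=0.1, n_chrom=2, seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """In-memory synthetic study: sumstats, LD reference, harmonized set, truth."""
    rng = np.random.default_rng(small_cfg.seed)
    gwas_dos, snp_info = simulate_genotypes(small_cfg, rng)
    y, truth = simulate_phenotype(gwas_dos, small_cfg, rng)
    sst = marginal_gwas(gwas_dos, y, snp_info)
    ref = simulate_reference(small_cfg, rng, snp_info=snp_info)
    records = pd.DataFrame(
        {
            "snp_id": sst["SNP"], "a1": sst["A1"], "a2": sst["A2"],
            "beta_raw": sst["BETA"], "p_value": sst["P"], "se": sst["SE"],
        }
    )
    bim = pd.DataFrame(
        {
            "chrom": snp_info["CHR"], "snp_id": snp_info["SNP"], "cm": 0,
            "pos": snp_info["BP"], "a1": snp_info["A1"], "a2": snp_info["A2"],
        }
    )
    harm = harmonize(records, ref.snp_info, bim, n=small_cfg.n_gwas)
    return {
        "cfg": small_cfg, "snp_info": snp_info, "sumstats": sst,
        "records": records, "bim": bim, "ref": ref, "harm": harm,
        "truth": truth,
    }
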