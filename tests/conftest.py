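import numpy as np
import pytest

import sexprs as sx


@pytest.fixture(scope="session")
def pipeline():
    """One moderate end-to-end dataset shared by GWAS/PRS/evaluation tests.

    300 variants in blocks of 25, 1,500 training individuals per sex, h²=0.3
    for both sexes, rg=0.8, 2% causal variants shared across sexes.
    """
    sizes = {
        ("F", "train"): 1500, ("M", "train"): 1500,
        ("F", "validation"): 500, ("M", "validation"): 500,
        ("F", "test"): 500, ("M", "test"): 500,
        ("F", "reference"): 500, ("M", "reference"): 500,
    }
    panel = sx.simulate_genotype_panel(m_variants=300, block_size=25, rho=0.6,
                                       cohort_sizes=sizes, seed=101)
    causal = sx.sample_causal_sets(300, p_causal=0.02, shared_fraction=1.0, seed=101)
    arch = sx.draw_effect_sizes(causal, h2_f=0.3, h2_m=0.3, rg=0.8, seed=101)
    pheno = sx.simulate_phenotypes(panel, arch, seed=101)
    ld = sx.estimate_ld(panel, cohort="reference")
    stats = {s: sx.run_gwas(panel, pheno, stratum=s) for s in ("F", "M", "ALL")}
    return {"panel": panel, "causal": causal, "arch": arch, "pheno": pheno,
            "ld": ld, "stats": stats}


@pytest.fixture(scope="session")
def noldpanel():
    """LD-free (rho=0) panel with phenotypes, for unbiasedness-style checks."""
    sizes = {
        ("F", "train"): 2000, ("M", "train"): 2000,
        ("F", "validation"): 500, ("M", "validation"): 500,
        ("F", "test"): 500, ("M", "test"): 500,
        ("F", "reference"): 500, ("M", "reference"): 500,
    }
    panel = sx.simulate_genotype_panel(m_variants=400, block_size=25, rho=0.0,
                                       cohort_sizes=sizes, seed=77)
    causal = sx.sample_causal_sets(400, p_causal=0.025, shared_fraction=1.0, seed=77)
    arch = sx.draw_effect_sizes(causal, h2_f=0.3, h2_m=0.3, rg=1.0, seed=77)
    pheno = sx.simulate_phenotypes(panel, arch, seed=77)
    ld = sx.estimate_ld(panel, cohort="reference")
    return {"panel": panel, "causal": causal, "arch": arch, "pheno": pheno, "ld": ld}


def identity_ld(m: int, block_size: int = 50, source_n: int = 10**6) -> sx.LDBlockMatrix:
    """LD-free block matrix (identity blocks) for closed-form oracles."""
    blocks = []
    for lo in range(0, m, block_size):
        hi = min(lo + block_size, m)
        blocks.append(((lo, hi), np.eye(hi - lo)))
    return sx.LDBlockMatrix(blocks=blocks, source_n=source_n, ridge_eps=0.0)
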