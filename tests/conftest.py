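import numpy as np
import pandas as pd
import pytest

from prsgxe.simulate import (
    GenotypeMatrix,
    SimulationParams,
    simulate_cohort_phenotypes,
    simulate_genotypes,
    simulate_gwas_sumstats,
)


@pytest.fixture(scope="session")
def tiny_params() -> SimulationParams:
    return SimulationParams(
        n_individuals=300, n_variants=60, ld_block_size=5, seed=42,
        missing_rate=0.02,
    )


@pytest.fixture(scope="session")
def tiny_genotypes(tiny_params) -> GenotypeMatrix:
    return simulate_genotypes(tiny_params)


@pytest.fixture(scope="session")
def tiny_sumstats(tiny_genotypes, tiny_params):
    return simulate_gwas_sumstats(tiny_genotypes.variants, tiny_params)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_genotypes, tiny_sumstats, tiny_params) -> pd.DataFrame:
    _, true_beta = tiny_sumstats
    return simulate_cohort_phenotypes(tiny_genotypes, true_beta, tiny_params)


def make_genotypes(dosages, chrom=None, pos=None, ref=None, alt=None, info=None):
    """Hand-build a GenotypeMatrix from a dosage array for toy tests."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    chrom = chrom if chrom is not None else [1] * m
    pos = pos if pos is not None else [1000 * (j + 1) for j in range(m)]
    ref = ref if ref is not None else ["A"] * m
    alt = alt if alt is not None else ["G"] * m
    info = info if info is not None else [0.99] * m
    meta = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "info": info,
        }
    )
    return GenotypeMatrix(
        dosages=d, variants=meta, samples=[f"I{i}" for i in range(n)]
    )
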