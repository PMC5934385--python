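import numpy as np
import pandas as pd
import pytest

from ssri_pgx import (
    EffectSpec,
    GeneModel,
    GenotypeMatrix,
    assign_sites_and_plates,
    inject_missingness,
    simulate_genotypes,
    simulate_hrsd,
)


@pytest.fixture(scope="session")
def small_gene():
    return GeneModel("TESTG", "1", 1_000_000, 1_100_000, n_variants=8, block_rho=0.0)


@pytest.fixture(scope="session")
def cohort():
    """A small two-site cohort with complete data: samples, genotypes, panel."""
    samples = assign_sites_and_plates(160, seed=11)
    genes = [
        GeneModel("GENEA", "1", 1_000_000, 1_100_000, n_variants=6, block_rho=0.4),
        GeneModel("GENEB", "2", 5_000_000, 5_200_000, n_variants=6, block_rho=0.4),
    ]
    gm = simulate_genotypes(160, genes, seed=12)
    gm = GenotypeMatrix(gm.dosages.set_axis(samples.index, axis=0), gm.variants)
    panel = simulate_hrsd(samples, gm, [], seed=13)
    return samples, gm, panel


@pytest.fixture(scope="session")
def cohort_missing(cohort):
    samples, gm, panel = cohort
    return samples, gm, inject_missingness(panel, seed=14)


def make_genotype_matrix(dosages: np.ndarray, chrom="1", start=100) -> GenotypeMatrix:
    """Wrap a plain samples x variants array (NaN allowed) as a GenotypeMatrix."""
    n, m = dosages.shape
    cols = [f"v{j + 1}" for j in range(m)]
    d = pd.DataFrame(
        dosages.astype(float),
        index=pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id"),
        columns=cols,
    )
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(start, start + m), "ref": "A", "alt": "C"},
        index=pd.Index(cols, name="variant_id"),
    )
    return GenotypeMatrix(d, variants)
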