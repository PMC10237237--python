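import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from breedcomp.genotype_io import GenotypeMatrix
from breedcomp.simdata import SimulationConfig, assemble_study_dataset


def make_genotypes(geno, chrom=None, pos=None, breed=None, ids=None):
    """Hand-build a GenotypeMatrix from a small array."""
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    ids = [f"s{i}" for i in range(n)] if ids is None else list(ids)
    samples = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    if breed is not None:
        samples["breed"] = list(breed)
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": pos},
        index=pd.Index([f"m{j}" for j in range(m)], name="snp_id"),
    )
    return GenotypeMatrix(geno, samples, markers)


@pytest.fixture(scope="session")
def small_dataset():
    """5 breeds, 1,200 SNPs on 3 chromosomes: quick but informative enough
    for purebred assignment to work."""
    cfg = SimulationConfig.scaled(
        n_breeds=5,
        n_snps=1200,
        n_chromosomes=3,
        n_training=40,
        n_validation=20,
        n_snp_selection=60,
        seed=42,
    )
    return assemble_study_dataset(cfg)
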